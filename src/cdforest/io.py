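"""Data readers/writers, run configuration, and result serialization."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .cd import CDResult
from .cdf import CDFResult
from .ekc import EKCResult
from .population import DataMatrix

__all__ = ["read_data", "write_data", "write_result", "result_to_dict", "load_study_config"]

SCHEMA_VERSION = 1


def read_data(path: str | Path, delimiter: str = ",") -> DataMatrix:
    """Read a numeric delimited-text data matrix (optional header row).

    Missing cells, non-numeric cells and constant columns are reported with
    row/column context rather than silently propagated.
    """
    path = Path(path)
    df = pd.read_csv(path, delimiter=delimiter, header="infer")
    # header="infer" treats an all-numeric first row as data only if every
    # column parses; re-read headerless when the inferred names are numeric.
    if all(str(c).replace(".", "", 1).lstrip("-").isdigit() for c in df.columns):
        df = pd.read_csv(path, delimiter=delimiter, header=None)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need at least 3 columns, found {df.shape[1]}")
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna())))
        raise ValueError(f"{path}: missing value at row {r + 1}, column {df.columns[c]!r}")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"{path}: non-numeric column(s) {bad}")
    values = df.to_numpy(dtype=float)
    const = np.flatnonzero(values.std(axis=0) == 0.0)
    if const.size:
        raise ValueError(f"{path}: constant column(s) {[df.columns[i] for i in const]}")
    return DataMatrix(values=values)


def write_data(data: DataMatrix, path: str | Path) -> None:
    """Write a data matrix as CSV with header V1..Vp."""
    cols = [f"V{i + 1}" for i in range(data.p)]
    pd.DataFrame(data.values, columns=cols).to_csv(path, index=False)


def _round_floats(obj: Any, sig: int = 12) -> Any:
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def result_to_dict(result: CDResult | CDFResult | EKCResult,
                   settings: Mapping[str, Any] | None = None,
                   seed: int | None = None) -> dict:
    """Serialize a retention result to a JSON-ready dictionary."""
    if isinstance(result, CDResult):
        body = {
            "method": "cd",
            "k_hat": result.k_hat,
            "p_values": list(result.p_values),
            "rmsr_means": result.rmsr_means,
            "censored": result.censored,
        }
    elif isinstance(result, CDFResult):
        body = {
            "method": "cdf",
            "k_hat": result.k_hat,
            "votes": result.votes.tolist(),
            "oob_accuracy": result.oob_accuracy,
            "training_size": result.training_size,
        }
    elif isinstance(result, EKCResult):
        body = {
            "method": "ekc",
            "k_hat": result.k_hat_floored,
            "k_hat_raw": result.k_hat,
            "references": result.references.tolist(),
        }
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")
    body["schema_version"] = SCHEMA_VERSION
    if settings is not None:
        body["settings"] = dict(settings)
    if seed is not None:
        body["seed"] = seed
    return _round_floats(body)


def write_result(result: CDResult | CDFResult | EKCResult, path: str | Path,
                 settings: Mapping[str, Any] | None = None,
                 seed: int | None = None) -> None:
    """Write a retention result as a JSON document."""
    Path(path).write_text(
        json.dumps(result_to_dict(result, settings=settings, seed=seed), indent=2) + "\n"
    )


STUDY_CONFIG_KEYS = {
    "factors", "sample_sizes", "vpf", "rho", "primary_bins", "cross_bins",
    "replications", "seed", "cd", "cdf",
}


def load_study_config(path: str | Path) -> dict:
    """Load and validate a study configuration (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: study config must be a mapping")
    unknown = set(cfg) - STUDY_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg
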