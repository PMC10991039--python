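"""Monte Carlo evaluation harness.

Runs the simulation study — design conditions x replications x retention
methods — with a paired design: each (condition, replication) cell generates
one data set, and every method/hyperparameter setting is applied to that same
data set.  Records are journaled to JSON lines so long runs are resumable,
and aggregation turns them into accuracy/bias tables and the CD-vs-CDF
agreement analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cd import CDSettings, run_cd
from .cdf import CDFSettings, run_cdf
from .ekc import run_ekc
from .population import ConditionSpec, DataMatrix, build_population, sample_data

__all__ = [
    "MethodSpec",
    "StudyRecord",
    "default_methods",
    "smoke_grid",
    "run_study",
    "aggregate",
    "agreement_analysis",
]

log = logging.getLogger(__name__)

CONDITION_FIELDS = ("k", "n", "vpf", "rho", "primary_bin", "cross_bin")


@dataclass(frozen=True)
class MethodSpec:
    """A retention method plus a hyperparameter setting, under one name."""

    name: str
    apply: Callable[[DataMatrix, np.random.Generator], int]


@dataclass(frozen=True)
class StudyRecord:
    """One simulation cell: condition, replication, method, estimate."""

    condition: ConditionSpec
    replication: int
    method: str
    k_true: int
    k_hat: int
    runtime_seconds: float = 0.0

    def to_row(self) -> dict:
        row = {f: getattr(self.condition, f) for f in CONDITION_FIELDS}
        row.update(
            replication=self.replication,
            method=self.method,
            k_true=self.k_true,
            k_hat=self.k_hat,
            runtime_seconds=self.runtime_seconds,
        )
        return row

    @staticmethod
    def from_row(row: Mapping) -> "StudyRecord":
        cond = ConditionSpec(**{f: row[f] for f in CONDITION_FIELDS})
        return StudyRecord(
            condition=cond,
            replication=int(row["replication"]),
            method=str(row["method"]),
            k_true=int(row["k_true"]),
            k_hat=int(row["k_hat"]),
            runtime_seconds=float(row.get("runtime_seconds", 0.0)),
        )


def default_methods(
    cd_settings: CDSettings | None = None,
    cdf_settings: CDFSettings | None = None,
) -> list[MethodSpec]:
    """CD, CDF and EKC under the given (or default) hyperparameters."""
    cd_s = cd_settings or CDSettings()
    cdf_s = cdf_settings or CDFSettings()
    return [
        MethodSpec(
            name=f"cd_a{cd_s.alpha:g}_r{cd_s.n_rep}",
            apply=lambda d, rng, s=cd_s: run_cd(d, s, rng).k_hat,
        ),
        MethodSpec(
            name=f"cdf_r{cdf_s.n_rep}_p{cdf_s.n_population}",
            apply=lambda d, rng, s=cdf_s: run_cdf(d, s, rng).k_hat,
        ),
        MethodSpec(name="ekc", apply=lambda d, rng: run_ekc(d).k_hat_floored),
    ]


def smoke_grid() -> list[ConditionSpec]:
    """A stratified 12-condition subset of the full design for quick studies.

    Four cells per true factor count, spanning both vpf levels, all three
    sample sizes, orthogonal and correlated factors, and all three primary
    loading bins, chosen so the known method contrasts (analytic criteria
    excel at clean one-factor structure; the forest approach at many
    correlated, weakly measured factors) are represented.
    """
    return [
        # k = 1: simple structure by definition; weighted towards few
        # variables and weak loadings, the hardest one-factor stratum
        ConditionSpec(k=1, n=250, vpf=4, primary_bin="small"),
        ConditionSpec(k=1, n=1000, vpf=4, primary_bin="small"),
        ConditionSpec(k=1, n=1000, vpf=4, primary_bin="medium"),
        ConditionSpec(k=1, n=500, vpf=7, primary_bin="large"),
        # k = 3
        ConditionSpec(k=3, n=500, vpf=4, rho=0.0, primary_bin="large", cross_bin="zero"),
        ConditionSpec(k=3, n=250, vpf=4, rho=0.2, primary_bin="medium", cross_bin="small"),
        ConditionSpec(k=3, n=500, vpf=7, rho=0.5, primary_bin="medium", cross_bin="zero"),
        ConditionSpec(k=3, n=1000, vpf=7, rho=0.2, primary_bin="small", cross_bin="small"),
        # k = 5
        ConditionSpec(k=5, n=500, vpf=7, rho=0.5, primary_bin="medium", cross_bin="small"),
        ConditionSpec(k=5, n=250, vpf=7, rho=0.5, primary_bin="small", cross_bin="small"),
        ConditionSpec(k=5, n=1000, vpf=7, rho=0.2, primary_bin="medium", cross_bin="zero"),
        ConditionSpec(k=5, n=500, vpf=4, rho=0.5, primary_bin="medium", cross_bin="small"),
    ]


def _cell_seed(master: np.random.SeedSequence, cond_idx: int, rep: int) -> np.random.SeedSequence:
    # Stable per-cell streams: independent of iteration order and worker count.
    return np.random.SeedSequence(entropy=master.entropy, spawn_key=(cond_idx, rep))


def run_study(
    conditions: Sequence[ConditionSpec],
    methods: Sequence[MethodSpec],
    replications: int,
    seed: int,
    journal_path: str | Path | None = None,
) -> list[StudyRecord]:
    """Run the paired Monte Carlo study.

    For every condition x replication, one population model and one data set
    are generated from a cell-specific seed stream; each method then receives
    the same data with its own derived stream, so method comparisons are
    paired.  When ``journal_path`` is given, finished cells found in the
    journal are skipped and new records appended, making runs resumable.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    master = np.random.SeedSequence(seed)
    done: set[tuple] = set()
    records: list[StudyRecord] = []
    journal = Path(journal_path) if journal_path is not None else None
    if journal is not None and journal.exists():
        for line in journal.read_text().splitlines():
            if not line.strip():
                continue
            rec = StudyRecord.from_row(json.loads(line))
            records.append(rec)
            done.add((rec.condition.label(), rec.replication, rec.method))

    out = journal.open("a") if journal is not None else None
    try:
        for ci, cond in enumerate(conditions):
            for rep in range(replications):
                cell_ss = _cell_seed(master, ci, rep)
                data_rng = np.random.default_rng(cell_ss.spawn(1)[0])
                pending = [m for m in methods
                           if (cond.label(), rep, m.name) not in done]
                if not pending:
                    continue
                model = build_population(cond, data_rng)
                data = sample_data(model, cond.n, data_rng)
                method_streams = cell_ss.spawn(len(methods) + 1)[1:]
                for m, ss in zip(methods, method_streams):
                    if (cond.label(), rep, m.name) in done:
                        continue
                    t0 = time.perf_counter()
                    try:
                        k_hat = int(m.apply(data, np.random.default_rng(ss)))
                    except Exception:
                        log.exception("cell failed: %s rep %d method %s",
                                      cond.label(), rep, m.name)
                        continue
                    rec = StudyRecord(
                        condition=cond, replication=rep, method=m.name,
                        k_true=cond.k, k_hat=k_hat,
                        runtime_seconds=time.perf_counter() - t0,
                    )
                    records.append(rec)
                    if out is not None:
                        out.write(json.dumps(rec.to_row()) + "\n")
                        out.flush()
    finally:
        if out is not None:
            out.close()
    return records


def records_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in records])
    if df.empty:
        raise ValueError("no study records")
    return df


def aggregate(
    records: Iterable[StudyRecord] | pd.DataFrame,
    by: Sequence[str] = ("method",),
) -> pd.DataFrame:
    """Accuracy, bias, and under-/overfactoring rates per group.

    Accuracy is the relative frequency of exact recovery (k_hat == k_true);
    bias the mean signed error k_hat - k_true.  Accuracy, underfactor and
    overfactor rates sum to 1 per group by construction.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    known = set(df.columns)
    unknown = [g for g in by if g not in known]
    if unknown:
        raise KeyError(f"unknown grouping key(s): {unknown}")
    err = df["k_hat"] - df["k_true"]
    work = df.assign(
        _correct=(err == 0).astype(float),
        _under=(err < 0).astype(float),
        _over=(err > 0).astype(float),
        _bias=err.astype(float),
    )
    grouped = work.groupby(list(by), observed=True)
    out = grouped.agg(
        accuracy=("_correct", "mean"),
        bias=("_bias", "mean"),
        underfactor_rate=("_under", "mean"),
        overfactor_rate=("_over", "mean"),
        n_cells=("_correct", "size"),
    ).reset_index()
    return out


def agreement_analysis(
    records: Iterable[StudyRecord] | pd.DataFrame,
    method_a: str,
    method_b: str,
) -> dict:
    """Compare two methods on the cells where both produced an estimate.

    Returns the overall agreement rate, the accuracy of the shared answer
    given agreement, and a per-difference table: for each level of
    k_hat_a - k_hat_b, its relative frequency and each method's conditional
    accuracy.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    keys = [*CONDITION_FIELDS, "replication"]
    a = df[df["method"] == method_a].set_index(keys)
    b = df[df["method"] == method_b].set_index(keys)
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if joined.empty:
        raise ValueError("no paired records for the two methods")
    diff = joined["k_hat_a"] - joined["k_hat_b"]
    agree = diff == 0
    rows = []
    for level, grp in joined.groupby(diff):
        rows.append({
            "khat_diff": int(level),
            "frequency": len(grp) / len(joined),
            "accuracy_a": float((grp["k_hat_a"] == grp["k_true_a"]).mean()),
            "accuracy_b": float((grp["k_hat_b"] == grp["k_true_a"]).mean()),
        })
    agreement_rate = float(agree.mean())
    if agree.any():
        acc_given_agreement = float(
            (joined.loc[agree, "k_hat_a"] == joined.loc[agree, "k_true_a"]).mean()
        )
    else:
        acc_given_agreement = float("nan")
    return {
        "method_a": method_a,
        "method_b": method_b,
        "n_pairs": int(len(joined)),
        "agreement_rate": agreement_rate,
        "accuracy_given_agreement": acc_given_agreement,
        "by_difference": pd.DataFrame(rows).sort_values("khat_diff").reset_index(drop=True),
    }
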