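"""Population factor models and multivariate-normal data simulation.

The evaluation study generates data from known factor structures: each of k
factors carries `vpf` indicator variables with a primary loading drawn from a
magnitude bin, optional cross-loadings on the remaining factors, and an
equicorrelated factor correlation matrix with off-diagonal ``rho``.  Observed
variables are standardized, so the implied covariance matrix is a correlation
matrix: ``Sigma = L @ Phi @ L.T + diag(uniquenesses)`` with unit diagonal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PRIMARY_BINS",
    "CROSS_BINS",
    "ConditionSpec",
    "PopulationModel",
    "DataMatrix",
    "build_population",
    "sample_data",
    "enumerate_grid",
    "InfeasibleModelError",
]

# Loading-magnitude bins for primary and cross-loadings (uniform sampling).
PRIMARY_BINS: dict[str, tuple[float, float]] = {
    "small": (0.35, 0.50),
    "medium": (0.50, 0.65),
    "large": (0.65, 0.80),
}
CROSS_BINS: dict[str, tuple[float, float]] = {
    "zero": (0.0, 0.0),
    "small": (0.0, 0.10),
    "medium": (0.10, 0.20),
}

#: Minimum admissible uniqueness; draws below this are rejected and resampled.
MIN_UNIQUENESS = 0.05
#: Retry budget for rejection sampling of admissible models.
MAX_MODEL_RETRIES = 100
#: Retry budget for a single variable's loading row (admissibility can be
#: rare in the most saturated bin/rho combinations, e.g. ~2% of draws for
#: k=5, rho=0.5, large primary and medium cross-loadings).
MAX_VARIABLE_RETRIES = 5000


class InfeasibleModelError(RuntimeError):
    """Raised when no admissible model is found within the retry budget."""


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design.

    Parameters
    ----------
    k : int
        True number of common factors.
    n : int
        Sample size of each simulated data set.
    vpf : int
        Variables (indicators) per factor; p = k * vpf.
    rho : float
        Inter-factor correlation (all off-diagonals of Phi).
    primary_bin : {"small", "medium", "large"}
        Bin from which primary loadings are drawn uniformly.
    cross_bin : {"zero", "small", "medium"}
        Bin for cross-loadings on non-primary factors.
    """

    k: int
    n: int
    vpf: int
    rho: float = 0.0
    primary_bin: str = "medium"
    cross_bin: str = "zero"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.vpf < 2:
            raise ValueError("vpf must be >= 2")
        if self.primary_bin not in PRIMARY_BINS:
            raise ValueError(f"unknown primary_bin {self.primary_bin!r}")
        if self.cross_bin not in CROSS_BINS:
            raise ValueError(f"unknown cross_bin {self.cross_bin!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.k == 1:
            if self.rho != 0.0:
                raise ValueError("rho is inapplicable for k=1 (must be 0)")
            if self.cross_bin != "zero":
                raise ValueError("cross-loadings are inapplicable for k=1")
        if self.n < self.p + 1:
            raise ValueError("n must exceed the number of variables")

    @property
    def p(self) -> int:
        return self.k * self.vpf

    def label(self) -> str:
        return (
            f"k{self.k}_n{self.n}_vpf{self.vpf}_rho{self.rho:g}"
            f"_{self.primary_bin}_{self.cross_bin}"
        )


@dataclass(frozen=True)
class PopulationModel:
    """A population factor model with implied correlation structure."""

    loadings: np.ndarray          # (p, k) standardized loadings
    factor_corr: np.ndarray       # (k, k) factor correlation matrix
    uniquenesses: np.ndarray      # (p,) unique variances

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def sigma(self) -> np.ndarray:
        """Implied correlation matrix L Phi L' + diag(psi)."""
        s = self.loadings @ self.factor_corr @ self.loadings.T
        s = s + np.diag(self.uniquenesses)
        # symmetrize against float round-off
        return (s + s.T) / 2.0


@dataclass(frozen=True)
class DataMatrix:
    """A complete numeric data set (n observations x p variables)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("data contains missing or non-finite entries")
        if np.any(v.std(axis=0) == 0.0):
            bad = np.flatnonzero(v.std(axis=0) == 0.0)
            raise ValueError(f"zero-variance column(s): {bad.tolist()}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _draw_variable_row(
    spec: ConditionSpec, factor: int, phi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one admissible loading row for a variable on the given factor.

    A variable's communality row' Phi row depends only on its own loadings,
    so rejection sampling row by row draws from exactly the same distribution
    as rejecting whole loading matrices — the rows are independent given Phi —
    while staying feasible in saturated cells where a jointly admissible
    matrix is vanishingly rare.
    """
    lo_p, hi_p = PRIMARY_BINS[spec.primary_bin]
    lo_c, hi_c = CROSS_BINS[spec.cross_bin]
    for _ in range(MAX_VARIABLE_RETRIES):
        row = np.zeros(spec.k)
        if hi_c > 0.0:
            row[:] = rng.uniform(lo_c, hi_c, size=spec.k)
        row[factor] = rng.uniform(lo_p, hi_p)
        if 1.0 - row @ phi @ row > MIN_UNIQUENESS:
            return row
    raise InfeasibleModelError(
        f"no admissible loading row for {spec!r} within {MAX_VARIABLE_RETRIES} draws"
    )


def build_population(spec: ConditionSpec, rng: np.random.Generator) -> PopulationModel:
    """Construct an admissible population model for a design cell.

    Loading rows are redrawn (bounded retries) until every uniqueness exceeds
    ``MIN_UNIQUENESS``; the assembled model is redrawn wholesale if the
    implied correlation matrix is not positive definite.

    Raises
    ------
    InfeasibleModelError
        If no admissible draw is found within the retry budgets, which
        signals an infeasible bin/rho combination rather than bad luck.
    """
    phi = np.full((spec.k, spec.k), spec.rho)
    np.fill_diagonal(phi, 1.0)
    for _ in range(MAX_MODEL_RETRIES):
        loadings = np.empty((spec.p, spec.k))
        for f in range(spec.k):
            for v in range(spec.vpf):
                loadings[f * spec.vpf + v] = _draw_variable_row(spec, f, phi, rng)
        uniq = 1.0 - np.einsum("ij,jk,ik->i", loadings, phi, loadings)
        model = PopulationModel(loadings=loadings, factor_corr=phi, uniquenesses=uniq)
        if np.linalg.eigvalsh(model.sigma)[0] > 1e-10:
            return model
    raise InfeasibleModelError(
        f"no positive-definite model for {spec!r} within {MAX_MODEL_RETRIES} retries"
    )


def sample_data(model: PopulationModel, n: int, rng: np.random.Generator) -> DataMatrix:
    """Draw n i.i.d. observations from N(0, Sigma(model))."""
    if n < model.p + 1:
        raise ValueError("n must exceed the number of variables")
    sigma = model.sigma
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise InfeasibleModelError("implied Sigma is not positive definite") from exc
    z = rng.standard_normal(size=(n, model.p))
    return DataMatrix(values=z @ chol.T)


def simulate_condition(
    spec: ConditionSpec, rng: np.random.Generator
) -> tuple[PopulationModel, DataMatrix]:
    """Convenience: build a population for a cell and draw one data set."""
    model = build_population(spec, rng)
    return model, sample_data(model, spec.n, rng)


# ---------------------------------------------------------------------------
# Design-grid enumeration
# ---------------------------------------------------------------------------

DEFAULT_GRID: dict[str, Sequence] = {
    "factors": (1, 3, 5),
    "sample_sizes": (250, 500, 1000),
    "vpf": (4, 7),
    "rho": (0.0, 0.2, 0.5),
    "primary_bins": ("small", "medium", "large"),
    "cross_bins": ("zero", "small", "medium"),
}


def enumerate_grid(config: Mapping[str, Sequence] | None = None) -> list[ConditionSpec]:
    """Enumerate the fully crossed simulation grid with exclusion rules.

    For single-factor cells the inter-factor correlation and cross-loading
    settings are inapplicable; those axes collapse to rho=0 / cross="zero",
    so the default grid yields 18 (k=1) + 324 (k in {3,5}) = 342 conditions.
    Ordering is deterministic (lexicographic in the axis order of the config).
    """
    cfg = dict(DEFAULT_GRID)
    if config:
        unknown = set(config) - set(DEFAULT_GRID)
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        cfg.update({k: tuple(v) for k, v in config.items()})
    specs: list[ConditionSpec] = []
    seen: set[tuple] = set()
    for k, n, vpf, rho, pb, cb in itertools.product(
        cfg["factors"], cfg["sample_sizes"], cfg["vpf"],
        cfg["rho"], cfg["primary_bins"], cfg["cross_bins"],
    ):
        if k == 1:
            rho, cb = 0.0, "zero"
        key = (k, n, vpf, rho, pb, cb)
        if key in seen:
            continue
        seen.add(key)
        specs.append(ConditionSpec(k=k, n=n, vpf=vpf, rho=rho,
                                   primary_bin=pb, cross_bin=cb))
    if not specs:
        raise ValueError("empty design grid")
    return specs
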