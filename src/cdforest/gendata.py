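"""Iterative generation of comparison-data populations.

Given an empirical data set and a candidate factor count k, the generator
builds a finite population of ``n_population`` observations whose correlation
matrix reproduces the empirical one as closely as a k-factor (unrotated,
orthogonal-component) model allows, while each variable's marginal
distribution is pinned to a bootstrap resample of the empirical column.

The algorithm iterates on an intermediate correlation matrix ``R_int``:

1. bootstrap each empirical column to length ``n_population`` — these sorted
   values are the fixed marginals for the whole run;
2. extract the leading k eigenpairs of ``R_int`` and form component loadings
   ``L = V_k * sqrt(max(lambda_k, 0))``, with unique variances
   ``1 - communality`` floored at zero;
3. generate scores as shared part + unique part from standard normals, then
   impose the marginals by rank substitution (the sorted bootstrap values
   replace the generated values in rank order, column by column);
4. score the candidate by the RMSR between the empirical correlations and the
   population's reproduced correlations (off-diagonal entries);
5. on improvement, keep the candidate and step ``R_int`` towards the residual
   (``R_int += step * (R_emp - R_rep)``); otherwise restore the best ``R_int``,
   halve the step and count a stalled trial.

The run stops after ``max_stalled_trials`` consecutive non-improvements or
``max_iterations`` iterations and returns the best candidate seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .population import DataMatrix

__all__ = [
    "GenDataSettings",
    "ComparisonPopulation",
    "generate_population",
    "draw_samples",
    "population_rmsr",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenDataSettings:
    """Tuning knobs of the population generator.

    ``n_population`` is the number of rows of each generated population
    (10000 by default). The iteration constants control the best-so-far
    search: at most ``max_iterations`` candidates, stopping early after
    ``max_stalled_trials`` consecutive failures to improve, with the residual
    step starting at ``initial_step`` and halving on each failure.
    """

    n_population: int = 10_000
    max_iterations: int = 300
    max_stalled_trials: int = 5
    initial_step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_population < 1 or self.max_iterations < 1 or self.max_stalled_trials < 1:
            raise ValueError("all counters must be >= 1")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")


@dataclass(frozen=True)
class ComparisonPopulation:
    """A generated comparison population and its goodness of fit."""

    values: np.ndarray            # (n_population, p)
    target_k: int
    achieved_rmsr: float
    iterations_used: int

    @property
    def n_population(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _offdiag_rmsr(a: np.ndarray, b: np.ndarray) -> float:
    """RMSR over the p(p-1)/2 unique off-diagonal correlation residuals."""
    iu = np.triu_indices_from(a, k=1)
    d = a[iu] - b[iu]
    return float(np.sqrt(np.mean(d * d)))


def population_rmsr(pop_values: np.ndarray, r_emp: np.ndarray) -> float:
    """Off-diagonal RMSR between a population's correlations and a target."""
    return _offdiag_rmsr(r_emp, np.corrcoef(pop_values, rowvar=False))


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0 and renormalize to unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w[0] >= 0.0:
        return r
    log.debug("intermediate correlation matrix drifted non-PSD "
              "(min eigenvalue %.3e); clipping", w[0])
    r2 = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(r2), 1e-12, None))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2


def _component_scores(
    r_int: np.ndarray, k: int, n_pop: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate n_pop rows under the k leading principal components of r_int."""
    w, v = np.linalg.eigh(r_int)
    order = np.argsort(w)[::-1]
    wk = np.clip(w[order[:k]], 0.0, None)
    loadings = v[:, order[:k]] * np.sqrt(wk)          # (p, k)
    uniq = np.clip(1.0 - np.sum(loadings**2, axis=1), 0.0, None)
    shared = rng.standard_normal((n_pop, k)) @ loadings.T
    unique = rng.standard_normal((n_pop, r_int.shape[0])) * np.sqrt(uniq)
    return shared + unique


def _impose_marginals(scores: np.ndarray, sorted_marginals: np.ndarray) -> np.ndarray:
    """Replace each column's values by the sorted bootstrap values in rank order."""
    out = np.empty_like(scores)
    order = np.argsort(scores, axis=0, kind="stable")
    rows = np.arange(scores.shape[0])
    for j in range(scores.shape[1]):
        out[order[rows, j], j] = sorted_marginals[:, j]
    return out


def generate_population(
    data: DataMatrix,
    k: int,
    settings: GenDataSettings,
    rng: np.random.Generator,
) -> ComparisonPopulation:
    """Generate a k-factor comparison population matching ``data``.

    Parameters
    ----------
    data : DataMatrix
        Empirical data whose correlation matrix and column marginals are the
        targets.
    k : int
        Number of components used to reproduce the correlation structure
        (1 <= k < p).
    settings : GenDataSettings
        Population size and iteration controls.
    rng : numpy.random.Generator
        Source of randomness; the run is deterministic given its state.
    """
    p = data.p
    if not 1 <= k < p:
        raise ValueError(f"k must satisfy 1 <= k < p (got k={k}, p={p})")
    r_emp = np.corrcoef(data.values, rowvar=False)
    if not np.all(np.isfinite(r_emp)):
        raise ValueError("empirical correlation matrix has non-finite entries")

    # Fixed marginals: one bootstrap resample per column, pre-sorted.
    n_pop = settings.n_population
    boot_idx = rng.integers(0, data.n, size=(n_pop, p))
    marginals = np.sort(data.values[boot_idx, np.arange(p)], axis=0)

    r_int = r_emp.copy()
    best_rmsr = np.inf
    best_pop: np.ndarray | None = None
    best_r_int = r_int.copy()
    step = settings.initial_step
    stalled = 0
    iterations = 0

    for iterations in range(1, settings.max_iterations + 1):
        r_int = _repair_psd(r_int)
        scores = _component_scores(r_int, k, n_pop, rng)
        pop = _impose_marginals(scores, marginals)
        r_rep = np.corrcoef(pop, rowvar=False)
        rmsr = _offdiag_rmsr(r_emp, r_rep)
        if rmsr < best_rmsr:
            best_rmsr = rmsr
            best_pop = pop
            best_r_int = r_int.copy()
            stalled = 0
            r_int = r_int + step * (r_emp - r_rep)
        else:
            r_int = best_r_int.copy()
            step /= 2.0
            stalled += 1
            if stalled >= settings.max_stalled_trials:
                break

    assert best_pop is not None
    return ComparisonPopulation(
        values=best_pop, target_k=k,
        achieved_rmsr=best_rmsr, iterations_used=iterations,
    )


def draw_samples(
    pop: ComparisonPopulation,
    n: int,
    n_rep: int,
    rng: np.random.Generator,
) -> list[DataMatrix]:
    """Draw ``n_rep`` simple random samples of ``n`` rows from a population.

    Each sample is drawn without replacement within itself; draws are
    independent across samples. Degenerate samples (a zero-variance column)
    raise immediately rather than propagating NaN correlations.
    """
    if n > pop.n_population:
        raise ValueError("sample size exceeds the population size")
    out: list[DataMatrix] = []
    for _ in range(n_rep):
        idx = rng.choice(pop.n_population, size=n, replace=False)
        out.append(DataMatrix(values=pop.values[idx]))
    return out
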