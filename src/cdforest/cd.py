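"""The classical comparison-data (CD) factor-retention method.

For each candidate factor count f = 1, 2, ... a comparison population is
generated that reproduces the empirical correlation matrix under f factors;
``n_rep`` samples of the empirical sample size are drawn from it, and the fit
of each sample is the RMSR between its eigenvalue profile and the empirical
one.  The candidate count advances while adding a factor still improves fit
significantly — a one-tailed Mann–Whitney U test asks whether the (f+1)-factor
RMSR values are stochastically smaller than the f-factor ones — and stops at
the first non-significant step, returning f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import correlation_matrix, eigen_profile
from .gendata import GenDataSettings, draw_samples, generate_population
from .population import DataMatrix

__all__ = ["CDSettings", "CDResult", "rmsr_eigen", "mann_whitney_less", "run_cd"]

log = logging.getLogger(__name__)

#: Combined-size threshold below which the U test is computed by exact
#: enumeration; larger samples use the tie-corrected normal approximation.
EXACT_U_LIMIT = 12


@dataclass(frozen=True)
class CDSettings:
    """Hyperparameters of the CD approach.

    ``alpha`` is the level of the internal Mann–Whitney U test, ``n_rep`` the
    number of comparison data sets per factor solution, ``n_population`` the
    size of each generated population, and ``k_max`` the cap on the candidate
    factor count.
    """

    alpha: float = 0.05
    n_rep: int = 1000
    n_population: int = 10_000
    k_max: int = 8
    gendata: GenDataSettings | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if min(self.n_rep, self.n_population, self.k_max) < 1:
            raise ValueError("n_rep, n_population and k_max must be positive")

    def gendata_settings(self) -> GenDataSettings:
        if self.gendata is not None:
            return self.gendata
        return GenDataSettings(n_population=self.n_population)


@dataclass(frozen=True)
class CDResult:
    """Outcome of a CD run: the estimate plus its internal diagnostics."""

    k_hat: int
    rmsr_distributions: list[np.ndarray]   # one length-n_rep array per candidate f
    p_values: list[float]                  # one per sequential comparison
    censored: bool = False                 # True when the loop hit k_max

    @property
    def rmsr_means(self) -> list[float]:
        return [float(np.mean(d)) for d in self.rmsr_distributions]


def rmsr_eigen(empirical: np.ndarray, comparison: np.ndarray) -> float:
    """Root mean squared residual between two eigenvalue profiles."""
    a = np.asarray(empirical, dtype=float)
    b = np.asarray(comparison, dtype=float)
    if a.shape != b.shape:
        raise ValueError("eigenvalue profiles must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mann_whitney_less(a: np.ndarray, b: np.ndarray) -> float:
    """One-tailed Mann–Whitney p-value for "b stochastically smaller than a".

    Exact by enumeration when the combined sample size is at most
    ``EXACT_U_LIMIT`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    combined = a.size + b.size
    no_ties = np.unique(np.concatenate([a, b])).size == combined
    method = "exact" if (combined <= EXACT_U_LIMIT and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="greater", method=method).pvalue)


def run_cd(
    data: DataMatrix,
    settings: CDSettings | None = None,
    rng: np.random.Generator | None = None,
) -> CDResult:
    """Estimate the number of factors of ``data`` with the CD approach.

    One population is generated per candidate f and reused for all of its
    ``n_rep`` samples, so sampling variability enters only through the draws.
    If every sequential test up to ``k_max`` is significant the estimate is
    returned as ``k_max`` with ``censored=True``.
    """
    settings = settings or CDSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if data.p < 3:
        raise ValueError("CD needs at least 3 variables")
    k_max = min(settings.k_max, data.p - 1)
    gen_settings = settings.gendata_settings()
    emp_eigs = eigen_profile(correlation_matrix(data))

    def rmsr_distribution(f: int) -> np.ndarray:
        pop = generate_population(data, f, gen_settings, rng)
        samples = draw_samples(pop, data.n, settings.n_rep, rng)
        return np.array([
            rmsr_eigen(emp_eigs, eigen_profile(correlation_matrix(s)))
            for s in samples
        ])

    distributions = [rmsr_distribution(1)]
    p_values: list[float] = []
    for f in range(1, k_max):
        distributions.append(rmsr_distribution(f + 1))
        p = mann_whitney_less(distributions[f - 1], distributions[f])
        p_values.append(p)
        if p >= settings.alpha:
            return CDResult(k_hat=f, rmsr_distributions=distributions,
                            p_values=p_values)
    log.info("CD reached k_max=%d without a non-significant step", k_max)
    return CDResult(k_hat=k_max, rmsr_distributions=distributions,
                    p_values=p_values, censored=True)
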