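"""The empirical Kaiser criterion (EKC).

A non-simulation baseline: each sample eigenvalue is compared to a reference
value that corrects the classical Kaiser threshold of 1 for sampling error
(through the variables-to-sample-size ratio p/n) and for the variance already
absorbed by preceding factors.  Factors are retained sequentially while the
eigenvalue exceeds its reference; the count stops at the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import correlation_matrix, eigen_profile
from .population import DataMatrix

__all__ = ["EKCResult", "ekc_references", "sequential_retain", "run_ekc"]


@dataclass(frozen=True)
class EKCResult:
    """EKC estimate with its reference eigenvalues.

    ``k_hat`` may be 0 when even the first eigenvalue falls below its
    reference; study aggregation floors the estimate at 1 (a retention
    criterion must propose at least one factor) while the raw value stays
    available here.
    """

    k_hat: int
    references: np.ndarray

    @property
    def k_hat_floored(self) -> int:
        return max(self.k_hat, 1)


def ekc_references(eigs: np.ndarray, n: int) -> np.ndarray:
    """Sample-size-adjusted reference eigenvalues.

    ref_j = max( [(p - sum_{i<j} lambda_i) / (p - j + 1)] * (1 + sqrt(p/n))^2, 1 )

    The leading factor is the average eigenvalue among the remaining ones
    after removing variance already accounted for; the multiplier
    (1 + sqrt(p/n))^2 is the asymptotic upper edge of the null eigenvalue
    distribution.  References never fall below 1.
    """
    eigs = np.asarray(eigs, dtype=float)
    p = eigs.size
    if p < 2:
        raise ValueError("need at least 2 eigenvalues")
    if n <= p:
        raise ValueError("reference formula requires n > p")
    edge = (1.0 + np.sqrt(p / n)) ** 2
    prior = np.concatenate([[0.0], np.cumsum(eigs)[:-1]])
    remaining_avg = (p - prior) / (p - np.arange(p))
    return np.maximum(remaining_avg * edge, 1.0)


def sequential_retain(eigs: np.ndarray, refs: np.ndarray) -> int:
    """Length of the initial run of eigenvalues strictly above their references.

    A stopping index, never a count of non-contiguous exceedances: the first
    eigenvalue at or below its reference ends the run.
    """
    exceeds = np.asarray(eigs) > np.asarray(refs)
    return int(np.argmin(exceeds)) if not exceeds.all() else int(exceeds.size)


def run_ekc(data: DataMatrix) -> EKCResult:
    """Apply the EKC to a data set."""
    eigs = eigen_profile(correlation_matrix(data))
    refs = ekc_references(eigs, data.n)
    return EKCResult(k_hat=sequential_retain(eigs, refs), references=refs)
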