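"""Eigenvalue profiles and the feature vector fed to the forest classifier.

The feature set summarises a data set through its sample correlation matrix:
the full eigenvalue profile, cumulative explained-variance proportions,
matrix norms, and inequality measures (Gini, Kolm) of the absolute bivariate
correlations, plus the raw dimensions n and p.  Comparison data sets and the
empirical data set are summarised by the same function so the classifier
sees them on an equal footing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .population import DataMatrix

__all__ = [
    "correlation_matrix",
    "eigen_profile",
    "gini",
    "kolm",
    "extract_features",
    "feature_names",
]

#: Cumulative-variance features are capped at this many leading eigenvalues
#: so the schema is stable across the study's range of p.
N_CUMVAR = 10


def correlation_matrix(data: DataMatrix) -> np.ndarray:
    """Pearson correlation matrix of a data set (unit diagonal, symmetric)."""
    r = np.corrcoef(data.values, rowvar=False)
    if not np.all(np.isfinite(r)):
        raise ValueError("correlation matrix has non-finite entries")
    return r


def eigen_profile(r: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of a full correlation matrix.

    Principal-component convention: the matrix keeps its unit diagonal, no
    communality reduction, so the eigenvalues sum to p.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return np.linalg.eigvalsh(r)[::-1]


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a nonnegative vector.

    G = sum_ij |x_i - x_j| / (2 m^2 mean(x)); 0 for a constant vector,
    approaching 1 as all mass concentrates in a single entry.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(x < 0):
        raise ValueError("values must be nonnegative")
    mean = x.mean()
    if mean == 0.0:
        raise ValueError("Gini undefined for an all-zero vector")
    # O(m log m) form via sorted values, equivalent to the double sum.
    xs = np.sort(x)
    m = x.size
    i = np.arange(1, m + 1)
    return float(np.sum((2 * i - m - 1) * xs) / (m * m * mean))


def kolm(values: np.ndarray, aversion: float = 1.0) -> float:
    """Kolm inequality index with the given inequality-aversion parameter.

    K = (1/a) * log( mean( exp(a * (mean(x) - x)) ) ); 0 for a constant
    vector.  The exponent is max-shifted to guard against overflow.
    """
    if aversion <= 0:
        raise ValueError("aversion must be positive")
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    z = aversion * (x.mean() - x)
    shift = z.max()
    return float((shift + np.log(np.mean(np.exp(z - shift)))) / aversion)


def feature_names(p: int) -> list[str]:
    """The fixed, ordered feature schema for data sets with p variables."""
    names = ["n", "p", "p_over_n"]
    names += [f"eig_{j + 1}" for j in range(p)]
    names += [f"cumvar_{j + 1}" for j in range(min(p, N_CUMVAR))]
    names += [
        "n_eig_gt_1",
        "n_eig_gt_0p7",
        "det_r",
        "norm_frobenius",
        "norm_colsum",
        "norm_maxabs",
        "norm_spectral",
        "abs_r_mean",
        "abs_r_sd",
        "abs_r_gini",
        "abs_r_kolm",
        "prop_abs_r_ge_0p3",
    ]
    return names


def extract_features(data: DataMatrix) -> pd.Series:
    """Compute the fixed-order feature vector of one data set.

    Returns a named Series following :func:`feature_names`; deterministic and
    invariant to row permutation of the input.
    """
    r = correlation_matrix(data)
    p = data.p
    eigs = eigen_profile(r)
    cumvar = np.cumsum(eigs) / p
    off = r[np.triu_indices(p, k=1)]
    abs_off = np.abs(off)

    vals = [float(data.n), float(p), p / data.n]
    vals += eigs.tolist()
    vals += cumvar[: min(p, N_CUMVAR)].tolist()
    vals += [
        float(np.sum(eigs > 1.0)),
        float(np.sum(eigs > 0.7)),
        float(np.prod(eigs)),                       # det(R) via eigenvalues
        float(np.linalg.norm(r, "fro")),
        float(np.max(np.sum(np.abs(r), axis=0))),   # induced 1-norm
        float(np.max(np.abs(r))),
        float(np.max(np.abs(eigs))),                # spectral norm of symmetric R
        float(abs_off.mean()),
        float(abs_off.std(ddof=0)),
        gini(abs_off) if abs_off.mean() > 0 else 0.0,
        kolm(abs_off),
        float(np.mean(abs_off >= 0.3)),
    ]
    return pd.Series(vals, index=feature_names(p))


def feature_table(datasets: list[DataMatrix]) -> pd.DataFrame:
    """Stack feature vectors of several same-shaped data sets into a table."""
    return pd.DataFrame([extract_features(d) for d in datasets])
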