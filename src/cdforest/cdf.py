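"""The comparison data forest (CDF) factor-retention method.

CDF keeps the CD approach's adaptive simulation step — comparison populations
generated under f = 1..k_max factors, each matching the empirical correlation
matrix and marginals — but replaces the sequential eigenvalue-fit test with a
classifier: features of the n_rep * k_max comparison samples, labeled by the
generating factor count, train a random forest that then predicts the number
of factors from the empirical data's features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import extract_features
from .gendata import GenDataSettings, draw_samples, generate_population
from .population import DataMatrix

__all__ = ["CDFSettings", "CDFResult", "build_training_table", "train_forest", "run_cdf"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CDFSettings:
    """Hyperparameters of the comparison data forest.

    ``n_rep`` comparison data sets are drawn per factor solution from
    populations of ``n_population`` rows, for candidate counts 1..``k_max``.
    The forest uses ``n_trees`` fully grown trees with floor(sqrt(#features))
    candidate features per split (the standard random-forest defaults).
    """

    n_rep: int = 1000
    n_population: int = 10_000
    k_max: int = 8
    n_trees: int = 500
    max_depth: int | None = None
    gendata: GenDataSettings | None = None

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.n_rep < 1 or self.n_population < 1 or self.n_trees < 1:
            raise ValueError("n_rep, n_population and n_trees must be positive")

    def gendata_settings(self) -> GenDataSettings:
        if self.gendata is not None:
            return self.gendata
        return GenDataSettings(n_population=self.n_population)


@dataclass(frozen=True)
class CDFResult:
    """Outcome of a CDF run: the estimate plus the forest's class votes."""

    k_hat: int
    votes: np.ndarray              # length-k_max class-vote proportions
    oob_accuracy: float
    training_size: int


def build_training_table(
    data: DataMatrix,
    settings: CDFSettings,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate comparison data under 1..k_max factors and extract features.

    Returns a table of exactly ``n_rep * k_max`` rows — ``n_rep`` per label —
    with the feature columns plus a ``label`` column holding the generating
    factor count.  All comparison samples share (n, p) with the empirical
    data set.
    """
    gen_settings = settings.gendata_settings()
    k_max = min(settings.k_max, data.p - 1)
    rows: list[pd.Series] = []
    labels: list[int] = []
    for f in range(1, k_max + 1):
        try:
            pop = generate_population(data, f, gen_settings, rng)
        except Exception as exc:
            raise RuntimeError(f"comparison-population generation failed for f={f}") from exc
        for sample in draw_samples(pop, data.n, settings.n_rep, rng):
            rows.append(extract_features(sample))
            labels.append(f)
    table = pd.DataFrame(rows).reset_index(drop=True)
    table["label"] = labels
    return table


def train_forest(
    table: pd.DataFrame,
    settings: CDFSettings,
    rng: np.random.Generator,
) -> RandomForestClassifier:
    """Fit the random forest on a labeled feature table.

    Each tree sees a bootstrap of the rows and floor(sqrt(#features))
    candidate features per split; trees are grown to purity unless
    ``max_depth`` caps them.  Out-of-bag accuracy is recorded on the fitted
    estimator (``oob_score_``).
    """
    labels = table["label"].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("training table must contain at least 2 distinct labels")
    x = table.drop(columns="label").to_numpy()
    forest = RandomForestClassifier(
        n_estimators=settings.n_trees,
        max_features="sqrt",
        max_depth=settings.max_depth,
        oob_score=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(x, labels)
    return forest


def run_cdf(
    data: DataMatrix,
    settings: CDFSettings | None = None,
    rng: np.random.Generator | None = None,
) -> CDFResult:
    """Estimate the number of factors of ``data`` with the comparison data forest.

    The estimate is the class with the largest share of tree votes on the
    empirical feature vector; vote ties resolve to the smallest factor count.
    """
    settings = settings or CDFSettings()
    rng = rng if rng is not None else np.random.default_rng()
    table = build_training_table(data, settings, rng)
    forest = train_forest(table, settings, rng)
    emp = extract_features(data).to_numpy()[None, :]
    votes = forest.predict_proba(emp)[0]
    # argmax on ties returns the first (= smallest) class: underfactoring-averse
    k_hat = int(forest.classes_[int(np.argmax(votes))])
    full_votes = np.zeros(settings.k_max)
    full_votes[np.asarray(forest.classes_, dtype=int) - 1] = votes
    return CDFResult(
        k_hat=k_hat,
        votes=full_votes,
        oob_accuracy=float(forest.oob_score_),
        training_size=len(table),
    )
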