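import numpy as np
import pytest

from cdforest import ConditionSpec, DataMatrix, PopulationModel, build_population, sample_data


@pytest.fixture
def rng():
    return np.random.default_rng(20230615)


def one_factor_model(loading: float = 0.8, p: int = 6) -> PopulationModel:
    """Single-factor model with equal loadings and simple structure."""
    loadings = np.full((p, 1), loading)
    return PopulationModel(
        loadings=loadings,
        factor_corr=np.eye(1),
        uniquenesses=1.0 - np.full(p, loading**2),
    )


def identity_model(p: int) -> PopulationModel:
    """Degenerate 'model' whose implied correlation matrix is the identity."""
    return PopulationModel(
        loadings=np.zeros((p, 1)),
        factor_corr=np.eye(1),
        uniquenesses=np.ones(p),
    )


@pytest.fixture
def three_factor_data(rng) -> DataMatrix:
    spec = ConditionSpec(k=3, n=500, vpf=4, rho=0.2,
                         primary_bin="large", cross_bin="zero")
    model = build_population(spec, rng)
    return sample_data(model, spec.n, rng)
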