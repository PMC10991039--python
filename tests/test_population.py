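import numpy as np
import pytest

from cdforest import (
    ConditionSpec,
    PopulationModel,
    build_population,
    enumerate_grid,
    sample_data,
)
from cdforest.population import CROSS_BINS, PRIMARY_BINS

from conftest import identity_model, one_factor_model


class TestPopulationModel:
    def test_single_factor_closed_form(self):
        # loadings 0.6 and 0.5 on one factor: r = 0.30, psi = 1 - loading^2
        model = PopulationModel(
            loadings=np.array([[0.6], [0.5]]),
            factor_corr=np.eye(1),
            uniquenesses=np.array([1 - 0.36, 1 - 0.25]),
        )
        sigma = model.sigma
        assert sigma[0, 1] == pytest.approx(0.30)
        assert np.allclose(np.diag(sigma), 1.0)
        assert model.uniquenesses == pytest.approx([0.64, 0.75])

    def test_orthogonal_simple_structure_is_block_diagonal(self, rng):
        spec = ConditionSpec(k=3, n=500, vpf=4, rho=0.0,
                             primary_bin="medium", cross_bin="zero")
        model = build_population(spec, rng)
        sigma = model.sigma
        assert model.p == 12
        for a in range(3):
            for b in range(3):
                block = sigma[a * 4:(a + 1) * 4, b * 4:(b + 1) * 4]
                if a != b:
                    assert np.all(block == 0.0)
                else:
                    assert np.all(np.abs(np.diag(block) - 1.0) < 1e-12)

    @pytest.mark.parametrize("primary_bin", ["small", "medium", "large"])
    @pytest.mark.parametrize("cross_bin", ["zero", "small", "medium"])
    def test_loadings_stay_in_bins(self, rng, primary_bin, cross_bin):
        spec = ConditionSpec(k=3, n=500, vpf=4, rho=0.2,
                             primary_bin=primary_bin, cross_bin=cross_bin)
        model = build_population(spec, rng)
        lo, hi = PRIMARY_BINS[primary_bin]
        clo, chi = CROSS_BINS[cross_bin]
        for f in range(3):
            block = model.loadings[f * 4:(f + 1) * 4]
            primary = block[:, f]
            cross = np.delete(block, f, axis=1)
            assert np.all((primary >= lo) & (primary <= hi))
            assert np.all((cross >= clo) & (cross <= chi))

    def test_hardest_cell_always_admissible(self):
        """The most demanding design cell (k=5, vpf=7, rho=.5, large primary,
        medium cross) must yield proper models across many seeded draws."""
        spec = ConditionSpec(k=5, n=1000, vpf=7, rho=0.5,
                             primary_bin="large", cross_bin="medium")
        for seed in range(1000):
            model = build_population(spec, np.random.default_rng(seed))
            assert np.all((model.uniquenesses > 0) & (model.uniquenesses < 1))
            assert np.linalg.eigvalsh(model.sigma)[0] > 0
            assert np.max(np.abs(np.diag(model.sigma) - 1.0)) < 1e-12

    def test_seeded_determinism(self):
        spec = ConditionSpec(k=3, n=250, vpf=4, rho=0.2,
                             primary_bin="small", cross_bin="small")
        m1 = build_population(spec, np.random.default_rng(7))
        m2 = build_population(spec, np.random.default_rng(7))
        assert np.array_equal(m1.loadings, m2.loadings)
        d1 = sample_data(m1, 250, np.random.default_rng(8))
        d2 = sample_data(m2, 250, np.random.default_rng(8))
        assert np.array_equal(d1.values, d2.values)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ConditionSpec(k=1, n=250, vpf=4, rho=0.2)
        with pytest.raises(ValueError):
            ConditionSpec(k=1, n=250, vpf=4, cross_bin="small")
        with pytest.raises(ValueError):
            ConditionSpec(k=3, n=10, vpf=4)  # n < p + 1


class TestSampleData:
    def test_shape_and_standardization(self, rng):
        spec = ConditionSpec(k=3, n=250, vpf=4, rho=0.2,
                             primary_bin="medium", cross_bin="zero")
        model = build_population(spec, rng)
        data = sample_data(model, 250, rng)
        assert data.values.shape == (250, 12)
        # population variance is 1; sample variances fluctuate around it
        assert np.all(np.abs(data.values.var(axis=0) - 1.0) < 0.5)

    def test_identity_population_has_small_sample_correlations(self):
        hits = 0
        for seed in range(50):
            data = sample_data(identity_model(6), 500, np.random.default_rng(seed))
            r = np.corrcoef(data.values, rowvar=False)
            off = np.abs(r[np.triu_indices(6, k=1)])
            hits += off.mean() < 0.1
        assert hits >= 49

    def test_large_n_consistency(self):
        model = one_factor_model(loading=0.8, p=2)
        data = sample_data(model, 100_000, np.random.default_rng(3))
        r = np.corrcoef(data.values, rowvar=False)[0, 1]
        assert r == pytest.approx(0.64, abs=0.01)


class TestEnumerateGrid:
    def test_default_grid_counts(self):
        grid = enumerate_grid()
        assert len(grid) == 342
        assert sum(1 for c in grid if c.k == 1) == 18
        assert sum(1 for c in grid if c.k in (3, 5)) == 324

    def test_multifactor_subgrid_count(self):
        grid = enumerate_grid({"factors": (3, 5)})
        assert len(grid) == 2 * 3 * 2 * 3 * 3 * 3

    def test_single_factor_collapses_inapplicable_axes(self):
        grid = enumerate_grid({"factors": (1,)})
        assert len(grid) == 3 * 2 * 3
        assert all(c.rho == 0.0 and c.cross_bin == "zero" for c in grid)

    def test_singleton_grid(self):
        grid = enumerate_grid({k: (v,) for k, v in {
            "factors": 3, "sample_sizes": 500, "vpf": 4, "rho": 0.2,
            "primary_bins": "medium", "cross_bins": "zero"}.items()})
        assert len(grid) == 1

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid({"nope": (1,)})
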