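"""Synthetic landscape generator: determinism, clines, neutral structure."""

import numpy as np
import pytest

from gfzones import SimulationConfig, simulate_climate_grid, simulate_dataset
from gfzones.simulate import (SimulationError, place_samples,
                              simulate_genotypes, VARIABLE_RANGES)


def weir_cockerham_fst(dosages: np.ndarray, pop_index: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham theta from diploid dosages (oracle)."""
    pops = np.unique(pop_index)
    r = len(pops)
    A = B = C = 0.0
    for j in range(dosages.shape[1]):
        d = dosages[:, j]
        n_i = np.array([np.sum(pop_index == p) for p in pops], dtype=float)
        p_i = np.array([d[pop_index == p].mean() / 2 for p in pops])
        h_i = np.array([np.mean(d[pop_index == p] == 1) for p in pops])
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


class TestClimateGrid:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(grid_shape=(30, 30), seed=1,
                               correlation_length=5)
        g1 = simulate_climate_grid(cfg)
        g2 = simulate_climate_grid(cfg)
        np.testing.assert_array_equal(g1.data, g2.data)

    def test_bands_within_plausible_ranges(self):
        cfg = SimulationConfig(grid_shape=(30, 30), seed=2,
                               correlation_length=5)
        grid = simulate_climate_grid(cfg)
        for name, (lo, hi) in VARIABLE_RANGES.items():
            band = grid.band(name)
            assert band.min() >= lo - 1e-9 and band.max() <= hi + 1e-9
        mat = grid.band("MAT")
        assert mat.min() == pytest.approx(-7.3) and \
            mat.max() == pytest.approx(10.3)

    def test_identity_correlation_gives_uncorrelated_bands(self):
        # near-white fields so the 10^4 cells are effectively independent
        # (smoothing divides the effective sample size by ~2*pi*l^2)
        cfg = SimulationConfig(grid_shape=(100, 100), seed=3,
                               correlation_length=0.6,
                               inter_variable_corr=0.0)
        grid = simulate_climate_grid(cfg)
        flat = grid.data.reshape(20, -1)
        corr = np.corrcoef(flat)
        off = corr[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_invalid_correlation_matrix_rejected(self):
        bad = np.full((20, 20), 1.0)  # rank 1, not PD
        cfg = SimulationConfig(inter_variable_corr=bad)
        with pytest.raises(SimulationError, match="positive definite"):
            simulate_climate_grid(cfg)


class TestPlaceSamples:
    def test_study_scale_uneven_design(self):
        cfg = SimulationConfig(grid_shape=(40, 40), n_populations=281,
                               total_samples=1906, correlation_length=6,
                               seed=4)
        grid = simulate_climate_grid(cfg)
        locations, table = place_samples(cfg, grid)
        assert len(locations) == 1906
        assert locations["population_id"].nunique() == 281
        assert table.n_samples == 1906

    def test_samples_inherit_cell_climate(self):
        cfg = SimulationConfig(grid_shape=(10, 10), n_populations=1,
                               samples_per_population=2,
                               correlation_length=2, seed=5)
        grid = simulate_climate_grid(cfg)
        locations, table = place_samples(cfg, grid)
        r, c = locations.loc[0, ["row", "col"]]
        np.testing.assert_allclose(table.matrix()[0], grid.data[:, r, c])
        np.testing.assert_allclose(table.matrix()[0], table.matrix()[1])

    def test_too_many_populations_rejected(self):
        cfg = SimulationConfig(grid_shape=(3, 3), n_populations=10,
                               correlation_length=1, seed=6)
        grid = simulate_climate_grid(cfg)
        with pytest.raises(SimulationError, match="valid cells"):
            place_samples(cfg, grid)


class TestGenotypes:
    def _sim(self, **kw):
        cfg = SimulationConfig(grid_shape=(40, 40), correlation_length=6,
                               **kw)
        grid, locations, table, genotypes, truth = simulate_dataset(cfg)
        return cfg, table, genotypes, truth

    def test_bit_reproducible(self):
        kw = dict(n_populations=10, samples_per_population=5, n_adaptive=4,
                  n_neutral=6, seed=7)
        _, _, g1, t1 = self._sim(**kw)
        _, _, g2, t2 = self._sim(**kw)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert t1.equals(t2)

    def test_flat_cline_matches_logistic_intercept(self):
        # b = 0: allele frequency ~ logistic(a) regardless of climate
        cfg = SimulationConfig(grid_shape=(40, 40), n_populations=100,
                               samples_per_population=20, n_adaptive=1,
                               n_neutral=0, slope_range=(0.0, 0.0),
                               intercept_range=(0.4, 0.4),
                               correlation_length=6, seed=8)
        _, _, table, genotypes, truth = (None, *simulate_dataset(cfg)[1:])
        p_hat = genotypes.dosages[:, 0].mean() / 2
        expected = 1 / (1 + np.exp(-0.4))
        # 2000 binomial(2, .) draws: 3 sigma ~ 0.023
        assert abs(p_hat - expected) < 0.025

    def test_strong_cline_orders_climate_deciles(self):
        cfg = SimulationConfig(grid_shape=(40, 40), n_populations=100,
                               samples_per_population=20, n_adaptive=5,
                               n_neutral=0, slope_range=(3.0, 3.0),
                               correlation_length=6, seed=9)
        grid, locations, table, genotypes, truth = simulate_dataset(cfg)
        for j in range(5):
            driver = truth.loc[j, "driver"]
            sign = np.sign(truth.loc[j, "slope"])
            z = table.values[driver].to_numpy()
            lo, hi = np.quantile(z, [0.1, 0.9])
            mean_top = genotypes.dosages[z >= hi, j].mean()
            mean_bot = genotypes.dosages[z <= lo, j].mean()
            assert sign * (mean_top - mean_bot) > 0.5

    def test_neutral_fst_matches_target(self):
        cfg = SimulationConfig(grid_shape=(40, 40), n_populations=50,
                               samples_per_population=20, n_adaptive=0,
                               n_neutral=200, fst=0.1,
                               correlation_length=6, seed=10)
        grid, locations, table, genotypes, truth = simulate_dataset(cfg)
        pop_index = np.asarray(
            [int(p[1:]) for p in genotypes.population_ids])
        theta = weir_cockerham_fst(genotypes.dosages, pop_index)
        assert 0.05 <= theta <= 0.15

    def test_large_n_frequency_convergence(self):
        # empirical frequency at a climate value -> logistic(a + b z)
        cfg = SimulationConfig(grid_shape=(40, 40), n_populations=50,
                               samples_per_population=200, n_adaptive=1,
                               n_neutral=0, slope_range=(2.0, 2.0),
                               intercept_range=(0.0, 0.0),
                               correlation_length=6, seed=12)
        grid, locations, table, genotypes, truth = simulate_dataset(cfg)
        driver = truth.loc[0, "driver"]
        b = truth.loc[0, "slope"]
        x = table.values[driver].to_numpy()
        z = (x - x.mean()) / x.std()
        # per population: 200 samples at one z value
        pops = np.asarray(genotypes.population_ids)
        errs = []
        for p in np.unique(pops):
            sel = pops == p
            expected = 1 / (1 + np.exp(-(b * z[sel][0])))
            errs.append(genotypes.dosages[sel, 0].mean() / 2 - expected)
        # binomial se at n=400 draws is <= 0.025; allow 4 sigma
        assert np.max(np.abs(errs)) < 0.1
        assert abs(np.mean(errs)) < 0.01

    def test_invalid_fst_rejected(self):
        with pytest.raises(SimulationError, match="F must be"):
            SimulationConfig(fst=1.5).validate()
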