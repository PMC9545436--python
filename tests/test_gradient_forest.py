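"""Gradient-forest aggregation: conservation laws, densities, turnover
oracles, and serialization."""

import numpy as np
import pandas as pd
import pytest

from gfzones import (GenotypeMatrix, cumulative_importance,
                     fit_gradient_forest, fit_snp_forest, overall_importance,
                     raw_importance_density, standardized_importance)
from gfzones.gradient_forest import (GFModel, GradientForestError,
                                     SNPModelFit, TurnoverFunction,
                                     aggregate_model, data_density)

from conftest import make_climate_table, random_climate


def make_fit(splits, oob_r2=0.5, snp_id="s", names=None):
    """Build an SNPModelFit from explicit (predictor, value, importance)."""
    if names is None:
        names = [f"x{j}" for j in range(20)]
    pred = np.array([s[0] for s in splits], dtype=int)
    vals = np.array([s[1] for s in splits], dtype=float)
    imps = np.array([s[2] for s in splits], dtype=float)
    return SNPModelFit(snp_id, oob_r2, 100, 1.0, False, pred, vals, imps,
                       list(names))


class TestFitSNPForest:
    def test_contract_errors(self):
        climate = random_climate(50)
        with pytest.raises(GradientForestError, match="constant"):
            fit_snp_forest(np.ones(50), climate)
        short = np.full(50, np.nan)
        short[:10] = [0, 1] * 5
        with pytest.raises(GradientForestError, match="complete cases"):
            fit_snp_forest(short, climate)

    def test_missing_dropped_not_imputed(self):
        rng = np.random.default_rng(0)
        climate = random_climate(200)
        y = rng.integers(0, 3, 200).astype(float)
        y[:40] = np.nan
        fit = fit_snp_forest(y, climate, n_trees=10, seed=1)
        assert fit.n_complete == 160

    def test_share_conservation(self):
        """Partitioned R2 shares sum to the SNP's OOB R2 (rel 1e-9)."""
        rng = np.random.default_rng(1)
        climate = random_climate(300, seed=2)
        X = climate.matrix()
        p = 1 / (1 + np.exp(-1.5 * (X[:, 0] - X[:, 0].mean())))
        y = rng.binomial(2, p).astype(float)
        fit = fit_snp_forest(y, climate, n_trees=50, seed=3)
        assert fit.oob_r2 > 0
        assert fit.r2_shares().sum() == pytest.approx(fit.oob_r2,
                                                      rel=1e-9)

    def test_tiny_forest_flagged_when_oob_sparse(self):
        rng = np.random.default_rng(2)
        climate = random_climate(60, seed=3)
        y = rng.integers(0, 3, 60).astype(float)
        fit = fit_snp_forest(y, climate, n_trees=1, seed=4)
        assert fit.flagged and fit.oob_r2 == 0.0 and not fit.retained


class TestDensities:
    def test_single_split_lands_in_its_bin(self):
        edges = np.linspace(0.0, 10.0, 6)  # bins of width 2
        fit = make_fit([(0, 4.5, 0.7)], oob_r2=0.7)
        I = raw_importance_density([fit], "x0", edges,
                                   normalize_per_snp=False)
        expected = np.zeros(5)
        expected[2] = 0.7
        np.testing.assert_allclose(I, expected)

    def test_additivity_before_weighting(self):
        edges = np.linspace(0.0, 1.0, 11)
        splits = [(0, 0.15, 0.2), (0, 0.85, 0.3)]
        one = raw_importance_density([make_fit(splits)], "x0", edges,
                                     normalize_per_snp=False)
        two = raw_importance_density([make_fit(splits), make_fit(splits)],
                                     "x0", edges, normalize_per_snp=False)
        np.testing.assert_allclose(two, 2 * one)

    def test_binned_density_equals_brute_force_tally(self):
        """Tiny forest: binned I(x) equals an exhaustive split tally."""
        rng = np.random.default_rng(5)
        climate = random_climate(100, seed=6)
        X = climate.matrix()
        y = rng.binomial(2, 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        fit = fit_snp_forest(y, climate, n_trees=3, seed=7)
        name = climate.variables[1]
        edges = np.linspace(X[:, 1].min(), X[:, 1].max(), 12)
        I = raw_importance_density([fit], name, edges,
                                   normalize_per_snp=False)
        # oracle: direct tally over the enumerated split list
        expected = np.zeros(len(edges) - 1)
        for p_idx, v, w in zip(fit.split_predictor, fit.split_value,
                               fit.split_importance):
            if p_idx != 1:
                continue
            b = min(np.searchsorted(edges, v, side="right") - 1,
                    len(expected) - 1)
            expected[b] += w
        np.testing.assert_allclose(I, expected)

    def test_data_density_integrates_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=500)
        edges = np.linspace(x.min(), x.max(), 102)
        d = data_density(x, edges)
        assert (d * np.diff(edges)).sum() == pytest.approx(1.0, rel=1e-9)


class TestStandardizedImportance:
    def test_hand_case(self):
        I = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        d = np.full(5, 0.2)
        f, flags = standardized_importance(I, d)
        np.testing.assert_allclose(f, [0, 5, 10, 5, 0])
        assert not flags.any()

    def test_uniform_density_proportional(self):
        rng = np.random.default_rng(9)
        I = rng.random(10)
        f, _ = standardized_importance(I, np.full(10, 0.37))
        np.testing.assert_allclose(f / I, np.full(10, 1 / 0.37))

    def test_importance_equal_density_gives_constant(self):
        d = np.array([0.1, 0.3, 0.4, 0.2])
        f, _ = standardized_importance(3.0 * d, d)
        np.testing.assert_allclose(f, 3.0)

    def test_floor_flags_sparse_bins(self):
        I = np.ones(4)
        d = np.array([1.0, 1.0, 1e-6, 0.5])
        f, flags = standardized_importance(I, d, floor=0.01)
        assert flags.tolist() == [False, False, True, False]
        assert f[2] == pytest.approx(1 / 0.01)  # floored denominator

    def test_mismatched_binning_rejected(self):
        with pytest.raises(GradientForestError, match="binnings differ"):
            standardized_importance(np.ones(4), np.ones(5))


class TestCumulativeImportance:
    def test_flat_zero_and_single_step(self):
        tf = cumulative_importance("x0", fit=make_fit([]))
        assert tf.total == 0.0
        fit = make_fit([(0, 2.5, 0.4)], oob_r2=0.4)
        tf = cumulative_importance("x0", fit=fit)
        assert tf(2.4, kind="step") == 0.0
        assert tf(2.5, kind="step") == pytest.approx(0.4)
        assert tf(99.0, kind="step") == pytest.approx(0.4)

    def test_staircase_matches_brute_force_scan(self):
        """Per-SNP curve == weighted tally of splits <= x at 100 points."""
        rng = np.random.default_rng(10)
        climate = random_climate(120, seed=11)
        X = climate.matrix()
        y = rng.binomial(2, 1 / (1 + np.exp(-3 * X[:, 4]))).astype(float)
        fit = fit_snp_forest(y, climate, n_trees=5, seed=12)
        assert fit.retained  # oracle below assumes a positive-R2 fit
        name = climate.variables[4]
        tf = cumulative_importance(name, fit=fit)
        # oracle weights: normalized so the predictor's splits sum to the
        # SNP's partitioned R2 share
        pi = 4
        sel = fit.split_predictor == pi
        raw = fit.split_importance[sel]
        share = fit.r2_shares()[pi]
        w = raw * (share / raw.sum())
        xs = fit.split_value[sel]
        scan = np.linspace(X[:, 4].min() - 1, X[:, 4].max() + 1, 100)
        expected = np.array([w[xs <= x].sum() for x in scan])
        np.testing.assert_allclose(tf(scan, kind="step"), expected,
                                   atol=1e-12)

    def test_monotone_from_zero(self, small_model):
        for p, tf in small_model.turnover.items():
            assert tf.values[0] == 0.0
            assert (np.diff(tf.values) >= -1e-12).all()
            assert np.isfinite(tf.values).all()

    def test_validation_rejects_decreasing(self):
        with pytest.raises(GradientForestError):
            TurnoverFunction("x", np.array([0.0, 1.0]),
                             np.array([0.5, 0.2]))


class TestOverallImportance:
    def test_single_predictor_forest(self):
        fit = make_fit([(2, 0.5, 1.0), (2, 0.7, 0.5)], oob_r2=0.31)
        s = overall_importance([fit], [f"x{j}" for j in range(20)])
        assert s.iloc[0] == pytest.approx(0.31)
        assert s.index[0] == "x2"
        assert (s.iloc[1:] == 0).all()

    def test_mean_over_retained_and_tie_break(self):
        names = [f"x{j}" for j in range(3)]
        a = make_fit([(0, 0.1, 1.0)], oob_r2=0.4, names=names)
        b = make_fit([(1, 0.2, 1.0)], oob_r2=0.4, names=names)
        s = overall_importance([a, b], names)
        # equal importances 0.2/0.2: alphabetical tie-break
        assert list(s.index) == ["x0", "x1", "x2"]
        assert s["x0"] == pytest.approx(0.2)


class TestModelAggregation:
    def test_turnover_totals_equal_overall_importance(self, small_model):
        for p in small_model.predictor_names:
            assert small_model.turnover[p].total == pytest.approx(
                float(small_model.overall_importance[p]), rel=1e-9, abs=1e-15)
        total_turnover = sum(small_model.turnover[p].total
                             for p in small_model.predictor_names)
        assert total_turnover == pytest.approx(
            float(small_model.overall_importance.sum()), rel=1e-9)

    def test_retained_all_positive_r2(self, small_model):
        assert small_model.n_retained >= 1
        assert all(f.oob_r2 > 0 for f in small_model.fits)
        assert small_model.n_input_snps == 20

    def test_deterministic_given_seed(self, small_landscape):
        g = small_landscape["genotypes"].subset_snps(
            small_landscape["genotypes"].snp_ids[:6])
        m1 = fit_gradient_forest(g, small_landscape["climate"], n_trees=20,
                                 seed=9)
        m2 = fit_gradient_forest(g, small_landscape["climate"], n_trees=20,
                                 seed=9)
        assert m1.retained_snp_ids == m2.retained_snp_ids
        for p in m1.predictor_names:
            np.testing.assert_array_equal(m1.turnover[p].values,
                                          m2.turnover[p].values)

    def test_zero_retained_is_explicit_empty_model(self):
        model = aggregate_model([], np.random.default_rng(0).normal(
            size=(50, 3)), ["a", "b", "c"], n_input_snps=5)
        assert model.n_retained == 0
        for p in model.predictor_names:
            assert model.turnover[p].total == 0.0

    def test_json_round_trip(self, small_model, tmp_path):
        path = small_model.to_json(tmp_path / "model.json")
        back = GFModel.from_json(path)
        assert back.n_retained == small_model.n_retained
        pd.testing.assert_series_equal(back.overall_importance,
                                       small_model.overall_importance)
        for p in small_model.predictor_names:
            np.testing.assert_allclose(back.turnover[p].values,
                                       small_model.turnover[p].values)
            np.testing.assert_allclose(back.standardized[p],
                                       small_model.standardized[p])
        # shares survive the round trip (drives downstream importances)
        np.testing.assert_allclose(
            np.array([f.r2_shares() for f in back.fits]),
            np.array([f.r2_shares() for f in small_model.fits]), atol=1e-12)


class TestRetentionContrast:
    def test_cline_snps_retained_over_pure_noise(self):
        """Strong-cline SNPs vs permuted (structureless) SNPs: the retained
        set is dominated by the cline SNPs (>= 5x retention rate)."""
        rng = np.random.default_rng(13)
        climate = random_climate(500, seed=14)
        X = climate.matrix()
        n_each = 40
        cols, ids = [], []
        for j in range(n_each):
            drv = rng.integers(0, 20)
            p = 1 / (1 + np.exp(-(2.5 * (X[:, drv] - X[:, drv].mean())
                                  / X[:, drv].std())))
            cols.append(rng.binomial(2, p).astype(float))
            ids.append(f"cline{j}")
        for j in range(n_each):
            cols.append(rng.permutation(cols[j]))
            ids.append(f"perm{j}")
        g = GenotypeMatrix(climate.sample_ids, ["p"] * 500, ids,
                           np.stack(cols, axis=1))
        model = fit_gradient_forest(g, climate, n_trees=200, seed=15)
        kept = set(model.retained_snp_ids)
        rate_cline = len([s for s in kept if s.startswith("cline")]) / n_each
        rate_perm = len([s for s in kept if s.startswith("perm")]) / n_each
        assert rate_cline >= 5 * max(rate_perm, 1 / n_each / 5)
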