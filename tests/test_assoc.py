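"""Association layer: frozen models, MLR, correlation, clustering, sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatuniformity import (
    FieldSimConfig,
    LinearModel,
    TraitRaster,
    anova_oneway,
    anova_twoway,
    bin_values,
    cluster_cultivars,
    correlate,
    degrade_resolution,
    evaluate_model,
    fit_mlr,
    load_frozen_model,
    pearson,
    pielou_index,
    shannon_entropy,
    simulate_trait_raster,
    simulate_yield_table,
    sweep_bin_width,
    sweep_gsd,
)


def zeros_for(model):
    return {p: 0.0 for p in model.predictor_names}


class TestFrozenModels:
    """The four shipped published regression models, digit for digit."""

    @pytest.mark.parametrize(
        "name, intercept, some_coefs",
        [
            ("yield_mean", -4.934,
             {"FM_JS": 4.421, "LM_FS": 1.808, "SM_LFS": -0.025, "PM_FS": -2.012}),
            ("biomass_mean", -8.566,
             {"FM_FS": -8.184, "LM_JS": 2.594, "SM_JS": -0.127, "PM_LFS": 0.371}),
            ("yield_index", 6.621,
             {"FE_JS": -0.290, "LJ_FS": -2.559, "SJ_LFS": 4.700, "PM_FS": -1.418}),
            ("biomass_index", 13.609,
             {"FE_LFS": -3.295, "LJ_JS": -7.823, "SJ_JS": 13.550, "PM_JS": -2.570}),
        ],
    )
    def test_coefficients_exact(self, name, intercept, some_coefs):
        m = load_frozen_model(name)
        assert len(m.predictor_names) == 12
        assert m.intercept == intercept
        coefs = dict(zip(m.predictor_names, m.coefficients))
        for k, v in some_coefs.items():
            assert coefs[k] == v

    def test_all_zero_prediction_is_intercept(self):
        for name in ("yield_mean", "biomass_mean", "yield_index", "biomass_index"):
            m = load_frozen_model(name)
            assert evaluate_model(m, zeros_for(m)) == m.intercept

    def test_unit_predictor_difference_is_coefficient(self):
        m = load_frozen_model("yield_index")
        vals = zeros_for(m)
        vals["LJ_FS"] = 1.0
        assert evaluate_model(m, vals) - m.intercept == pytest.approx(-2.559)

    def test_missing_predictor_named(self):
        m = load_frozen_model("yield_index")
        vals = zeros_for(m)
        del vals["SJ_JS"]
        with pytest.raises(KeyError, match="SJ_JS"):
            evaluate_model(m, vals)

    def test_unknown_model_name(self):
        with pytest.raises(ValueError, match="unknown frozen model"):
            load_frozen_model("eq5")


class TestEvaluateModel:
    def test_exact_arithmetic_contract(self):
        m = LinearModel(("a", "b"), (2.0, -3.0), 1.0, "yield")
        assert evaluate_model(m, {"a": 2.0, "b": 1.0, "extra": 99}) == 2.0

    def test_coefficient_count_enforced(self):
        with pytest.raises(ValueError, match="coefficient"):
            LinearModel(("a", "b"), (1.0,), 0.0, "yield")


class TestFitMLR:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(0, 1, (60, 3)), columns=["u", "v", "w"])
        beta = np.array([2.0, -1.5, 0.7])
        y = X.to_numpy() @ beta + 4.0
        model, report = fit_mlr(X, pd.Series(y, name="yield_mg_ha"), seed=1)
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-8)
        assert model.intercept == pytest.approx(4.0, abs=1e-8)
        assert report.r2_validation == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(0, 1, (80, 4)), columns=list("abcd"))
        y = X.to_numpy() @ [1.0, 2.0, -1.0, 0.5] + rng.normal(0, 0.3, 80)
        model, report = fit_mlr(X, pd.Series(y), split=0.7, seed=2)
        from sklearn.model_selection import train_test_split

        idx_tr, _ = train_test_split(np.arange(80), train_size=0.7, random_state=2)
        A = np.column_stack([np.ones(len(idx_tr)), X.to_numpy()[idx_tr]])
        beta = np.linalg.solve(A.T @ A, A.T @ y[idx_tr])
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_orthogonal_response_r2_near_zero(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(0, 1, 200)})
        y = rng.normal(0, 1, 200)  # independent of x
        _, report = fit_mlr(X, pd.Series(y), seed=0)
        assert abs(report.r2_train) < 0.1

    def test_same_seed_same_fit(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(0, 1, 40), "z": rng.normal(0, 1, 40)})
        y = pd.Series(rng.normal(0, 1, 40))
        m1, r1 = fit_mlr(X, y, seed=7)
        m2, r2 = fit_mlr(X, y, seed=7)
        assert m1.coefficients == m2.coefficients
        assert r1 == r2

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": np.arange(30.0), "b": 2 * np.arange(30.0)})
        with pytest.raises(ValueError, match="b"):
            fit_mlr(X, pd.Series(np.arange(30.0)), seed=0)

    def test_too_few_rows(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="rows"):
            fit_mlr(X, pd.Series(np.ones(3)), seed=0)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson(x, -x + 5)[0] == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        r, n = pearson(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and n == 10

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        r, n = pearson(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    def test_long_table_grouping(self):
        table = pd.DataFrame(
            {
                "plot_id": ["p0", "p1", "p2", "p3"] * 2,
                "stage": ["FS"] * 8,
                "trait": ["LAI"] * 8,
                "index": ["pielou"] * 4 + ["mean"] * 4,
                "value": [0.1, 0.2, 0.3, 0.4, 3.0, 3.1, 3.2, 3.3],
            }
        )
        out = pd.DataFrame(
            {"plot_id": ["p0", "p1", "p2", "p3"],
             "yield_mg_ha": [4.0, 3.0, 2.0, 1.0],
             "biomass_mg_ha": [8.0, 6.0, 4.0, 2.0]}
        )
        res = correlate(table, out)
        row = res[(res["index"] == "pielou") & (res.outcome == "yield_mg_ha")]
        assert row["r"].iloc[0] == pytest.approx(-1.0)
        assert set(res["index"]) == {"pielou", "mean"}

    def test_sign_recovery_from_simulator(self):
        """Planted b_uniformity > 0 over 100 plots: r(Pielou LAI, yield) < 0."""
        cfg = FieldSimConfig(n_plots=100, seed=13)
        pj, mn = [], []
        for p in range(100):
            v = simulate_trait_raster(cfg, "LAI", p, stage="FS").valid_values()
            pj.append(pielou_index(bin_values(v, 0.5)))
            mn.append(v.mean())
        out = simulate_yield_table(cfg, np.array(pj), np.array(mn))
        r, n = pearson(np.array(pj), out["yield_mg_ha"].to_numpy())
        assert n == 100 and r < 0


class TestClusteringAnova:
    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(1)
        means = pd.DataFrame(
            {
                "yield_mg_ha": np.concatenate(
                    [rng.normal(8.6, 0.2, 10), rng.normal(6.7, 0.2, 10),
                     rng.normal(4.9, 0.2, 10)]
                ),
                "biomass_mg_ha": np.concatenate(
                    [rng.normal(18.2, 0.4, 10), rng.normal(15.0, 0.4, 10),
                     rng.normal(11.3, 0.4, 10)]
                ),
            },
            index=[f"cv{i}" for i in range(30)],
        )
        labels, table = cluster_cultivars(means, k=3)
        assert list(labels[:10]) == ["C1"] * 10
        assert list(labels[10:20]) == ["C2"] * 10
        assert list(labels[20:]) == ["C3"] * 10
        # labels ordered by descending mean yield
        m = table[("yield_mg_ha", "mean")]
        assert m["C1"] > m["C2"] > m["C3"]

    def test_single_cluster(self):
        means = pd.DataFrame(
            {"yield_mg_ha": [1.0, 2.0], "biomass_mg_ha": [2.0, 3.0]}
        )
        labels, _ = cluster_cultivars(means, k=1)
        assert set(labels) == {"C1"}

    def test_duplicated_rows_cluster_together(self):
        means = pd.DataFrame(
            {"yield_mg_ha": [8.0, 8.0, 4.0, 4.1], "biomass_mg_ha": [16.0, 16.0, 9.0, 9.2]}
        )
        labels, _ = cluster_cultivars(means, k=2)
        assert labels.iloc[0] == labels.iloc[1]

    def test_k_larger_than_n_raises(self):
        means = pd.DataFrame({"yield_mg_ha": [1.0], "biomass_mg_ha": [2.0]})
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cultivars(means, k=3)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        F, p_f = anova_oneway(
            np.concatenate([a, b]), np.array(["a"] * 15 + ["b"] * 12)
        )
        t, p_t = stats.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_large_effect_tiny_p(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        _, p = anova_oneway(vals, np.repeat(["a", "b"], 30))
        assert p < 1e-6

    def test_single_level_factor_raises(self):
        with pytest.raises(ValueError, match="two levels"):
            anova_oneway(np.arange(5.0), np.array(["a"] * 5))

    def test_twoway_main_effects(self):
        rng = np.random.default_rng(4)
        years = np.tile(["y1", "y2"], 40)
        cult = np.repeat([f"c{i}" for i in range(40)], 2)
        lj = rng.normal(0.4, 0.05, 80) + np.where(years == "y2", 0.3, 0.0)
        df = pd.DataFrame({"lj": lj, "year": years, "cultivar": cult})
        table = anova_twoway(df, "lj", "year", "cultivar")
        p_year = table.loc[table.index.str.contains("year"), "PR(>F)"].iloc[0]
        assert p_year < 1e-6

    def test_twoway_rejects_single_level(self):
        df = pd.DataFrame({"lj": [1.0, 2.0], "year": ["y1", "y1"], "cv": ["a", "b"]})
        with pytest.raises(ValueError, match="year"):
            anova_twoway(df, "lj", "year", "cv")


@pytest.fixture(scope="module")
def simulated_field():
    """100 plots, their flowering-stage LAI rasters and simulated outcomes."""
    cfg = FieldSimConfig(n_plots=100, seed=3)
    rasters = {
        f"plot_{p:03d}": simulate_trait_raster(cfg, "LAI", p, stage="FS")
        for p in range(100)
    }
    pj = np.array(
        [pielou_index(bin_values(r.valid_values(), 0.5)) for r in rasters.values()]
    )
    mn = np.array([r.valid_values().mean() for r in rasters.values()])
    outcomes = simulate_yield_table(cfg, pj, mn, plot_ids=sorted(rasters))
    return rasters, outcomes


class TestSweeps:
    def test_bin_width_degenerate_is_undefined(self, simulated_field):
        rasters, outcomes = simulated_field
        res = sweep_bin_width(rasters, outcomes, widths=[100.0])
        assert np.isnan(res.r("pielou", 100.0))  # S = 1 everywhere

    def test_shannon_nonincreasing_on_nested_grids(self, simulated_field):
        """Exact coarsening property on nested bins 0.25 -> 0.5 -> 1."""
        rasters, _ = simulated_field
        for r in list(rasters.values())[:10]:
            v = r.valid_values()
            hs = [shannon_entropy(bin_values(v, w)) for w in (0.25, 0.5, 1.0)]
            assert hs[0] >= hs[1] - 1e-12 >= hs[2] - 2e-12

    def test_fine_width_correlates_stronger_than_coarse(self, simulated_field):
        rasters, outcomes = simulated_field
        res = sweep_bin_width(rasters, outcomes, widths=(0.5, 7.5))
        r_fine = res.r("pielou", 0.5)
        r_coarse = res.r("pielou", 7.5)
        mag_coarse = 0.0 if np.isnan(r_coarse) else abs(r_coarse)
        assert abs(r_fine) >= mag_coarse

    def test_gsd_degradation_weakens_correlation(self, simulated_field):
        rasters, outcomes = simulated_field
        res = sweep_gsd(rasters, outcomes, factors=(1, 2, 4, 8))
        mags = [abs(res.r("pielou", 0.03 * f)) for f in (1, 2, 4, 8)]
        assert all(a >= b - 0.05 for a, b in zip(mags, mags[1:]))
        assert mags[0] > mags[-1]


class TestDegradeResolution:
    def _raster(self, values, mask=None):
        values = np.asarray(values, float)
        mask = np.ones(values.shape, bool) if mask is None else mask
        return TraitRaster(values=values, mask=mask, gsd_m=0.03, trait="LAI")

    def test_factor_one_identity(self):
        r = self._raster(np.arange(12.0).reshape(3, 4))
        out = degrade_resolution(r, 1)
        np.testing.assert_array_equal(out.values, r.values)
        assert out.gsd_m == r.gsd_m

    def test_constant_raster_stays_constant(self):
        r = self._raster(np.full((8, 8), 2.5))
        for f in (2, 4):
            assert np.all(degrade_resolution(r, f).values == 2.5)

    def test_checkerboard_averages_to_half(self):
        vals = np.indices((6, 6)).sum(axis=0) % 2
        out = degrade_resolution(self._raster(vals), 2)
        np.testing.assert_array_equal(out.values, np.full((3, 3), 0.5))

    def test_mean_preserved_when_blocks_divide(self):
        rng = np.random.default_rng(0)
        r = self._raster(rng.uniform(0, 5, (12, 16)))
        out = degrade_resolution(r, 4)
        assert out.values.mean() == pytest.approx(r.values.mean(), abs=1e-12)
        assert out.gsd_m == pytest.approx(0.12)

    def test_invalid_blocks_and_trailing_pixels(self):
        mask = np.ones((5, 5), bool)
        mask[:2, :2] = False  # the whole first 2x2 block is invalid
        r = self._raster(np.ones((5, 5)), mask)
        out = degrade_resolution(r, 2)
        assert out.shape == (2, 2)  # trailing row/col dropped
        assert not out.mask[0, 0] and out.mask[1, 1]

    def test_factor_exceeding_raster_raises(self):
        with pytest.raises(ValueError, match="factor"):
            degrade_resolution(self._raster(np.ones((4, 4))), 5)


class TestAnovaCalibration:
    def test_type_one_error_calibrated(self):
        """Under the null (equal group means), the ANOVA p-value is uniform:
        rejection rate at alpha = 0.05 within 3 binomial s.e. over 1,000 reps,
        and the p-value distribution passes a KS uniformity check."""
        rng = np.random.default_rng(99)
        labels = np.repeat(["g1", "g2", "g3"], 10)
        pvals = []
        for _ in range(1000):
            values = rng.normal(0, 1, 30)
            pvals.append(anova_oneway(values, labels)[1])
        pvals = np.asarray(pvals)
        rate = float(np.mean(pvals < 0.05))
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) <= 3 * se
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
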