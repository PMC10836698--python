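import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from betaforest.errors import InsufficientDataError, ZeroVarianceError
from betaforest.regression import (
    FIT_TABLE_COLUMNS,
    ModelSpec,
    fit_model_grid,
    fit_random_intercept,
    fit_single_model,
    standardize_columns,
    weighted_mean_sd,
)
from conftest import make_bivariate


class TestStandardizeColumns:
    def test_symmetric_three_point(self):
        out = standardize_columns(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), ["a"])
        assert out["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_column_errors_naming_column(self):
        with pytest.raises(ZeroVarianceError, match="zero-variance variable.*'a'"):
            standardize_columns(pd.DataFrame({"a": [5.0, 5.0, 5.0]}), ["a"])

    def test_weighted_hand_oracle(self):
        # oracle: explicit weighted mean/SD formulas evaluated here, not via the library path
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([1.0, 1.0, 1.0, 3.0])
        v1, v2 = w.sum(), (w**2).sum()
        mean = (w * vals).sum() / v1
        sd = np.sqrt((w * (vals - mean) ** 2).sum() / (v1 - v2 / v1))
        out = standardize_columns(pd.DataFrame({"a": vals, "w": w}), ["a"], weights="w")
        np.testing.assert_allclose(out["a"], (vals - mean) / sd, atol=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_output_moments_are_zero_one(self, weighted):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(5, 3, 200), "w": rng.uniform(0.5, 4, 200)})
        wname = "w" if weighted else None
        out = standardize_columns(df, ["a"], weights=wname)
        m, s = weighted_mean_sd(out["a"].to_numpy(), df["w"].to_numpy() if weighted else None)
        assert abs(m) < 1e-10
        assert abs(s - 1.0) < 1e-10

    def test_nonpositive_weight_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "w": [1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="strictly positive"):
            standardize_columns(df, ["a"], weights="w")

    def test_input_not_mutated(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        standardize_columns(df, ["a"])
        assert df["a"].tolist() == [1.0, 2.0, 3.0]


class TestFitSingleModel:
    def test_hand_oracle_pearson(self):
        # r = 8 / sqrt(10 * 10) = 0.80 computed from deviations by hand
        d = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        fit = fit_single_model(d, ModelSpec("y", "x"))
        assert fit.beta == pytest.approx(0.80, abs=1e-12)
        assert fit.n_obs == 5
        assert fit.ci_lower <= fit.beta <= fit.ci_upper

    def test_perfect_inverse_fit_degenerate(self):
        x = np.arange(10.0)
        d = pd.DataFrame({"x": x, "y": -x})
        fit = fit_single_model(d, ModelSpec("y", "x"))
        assert fit.beta == pytest.approx(-1.0, abs=1e-12)
        assert fit.degenerate
        assert fit.se == 0.0
        assert fit.p_value == 0.0
        assert (fit.ci_lower, fit.ci_upper) == (fit.beta, fit.beta)

    def test_beta_equals_pearson_r(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = pd.DataFrame(rng.standard_normal((50, 2)), columns=["x", "y"])
            fit = fit_single_model(d, ModelSpec("y", "x"))
            r = np.corrcoef(d["x"], d["y"])[0, 1]
            assert fit.beta == pytest.approx(r, abs=1e-10)

    def test_swap_outcome_predictor_symmetry(self):
        d = make_bivariate(0.3, 80, 5)
        a = fit_single_model(d, ModelSpec("y", "x"))
        b = fit_single_model(d, ModelSpec("x", "y"))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        d = make_bivariate(0.4, 100, 9)
        d["w"] = rng.uniform(0.5, 3.0, 100)
        a = fit_single_model(d, ModelSpec("y", "x", weight_name="w"))
        d2 = d.assign(w=d["w"] * 137.5)
        b = fit_single_model(d2, ModelSpec("y", "x", weight_name="w"))
        for field in ("beta", "se", "t_stat", "p_value", "ci_lower", "ci_upper"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-10)

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (50, 500, 5000):
            d = make_bivariate(0.25, n, 13)
            fit = fit_single_model(d, ModelSpec("y", "x"))
            widths.append(fit.ci_upper - fit.ci_lower)
        assert widths[0] > widths[1] > widths[2]

    @pytest.mark.parametrize("beta0", [-0.3, 0.0, 0.25])
    def test_ci_coverage(self, beta0):
        cover = sum(
            (lambda f: f.ci_lower <= beta0 <= f.ci_upper)(
                fit_single_model(make_bivariate(beta0, 500, seed), ModelSpec("y", "x"))
            )
            for seed in range(100)
        )
        assert cover >= 90

    def test_insufficient_data(self):
        d = pd.DataFrame({"x": [1.0, 2.0, np.nan], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            fit_single_model(d, ModelSpec("y", "x"))

    def test_listwise_deletion(self):
        d = pd.DataFrame({"x": [1, 2, 3, 4, np.nan], "y": [2, 1, 4, 3, 5.0]})
        fit = fit_single_model(d, ModelSpec("y", "x"))
        assert fit.n_obs == 4

    def test_zero_variance_propagates(self):
        d = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ZeroVarianceError):
            fit_single_model(d, ModelSpec("y", "x"))

    def test_single_level_cluster_falls_back(self, caplog):
        d = make_bivariate(0.3, 50, 3).assign(g="only")
        plain = fit_single_model(d, ModelSpec("y", "x"))
        with caplog.at_level("WARNING"):
            clustered = fit_single_model(d, ModelSpec("y", "x", cluster_name="g"))
        assert "single level" in caplog.text
        assert clustered.beta == pytest.approx(plain.beta, abs=1e-12)
        assert clustered.se == pytest.approx(plain.se, abs=1e-12)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "y")
        with pytest.raises(ValueError):
            ModelSpec("y", "x", conf_level=1.0)


class TestRandomIntercept:
    def test_matches_statsmodels_mixedlm(self):
        # dual route: independent REML implementation in statsmodels
        rng = np.random.default_rng(3)
        g = np.repeat(np.arange(40), 15)
        x = rng.standard_normal(600)
        y = 0.4 * x + rng.normal(0, 0.7, 40)[g] + rng.standard_normal(600)
        beta, se = fit_random_intercept(y, x, g)
        ref = smf.mixedlm("y ~ x", pd.DataFrame({"y": y, "x": x, "g": g}), groups=g).fit(reml=True)
        assert beta == pytest.approx(ref.params["x"], abs=1e-5)
        assert se == pytest.approx(ref.bse["x"], abs=1e-4)

    def test_no_cluster_variance_close_to_ols(self):
        # random grouping carries no signal, so the REML fit collapses to OLS
        d = make_bivariate(0.3, 200, 17)
        g = np.random.default_rng(0).permutation(np.arange(200) % 10)
        beta, _ = fit_random_intercept(d["y"].to_numpy(), d["x"].to_numpy(), g)
        ols_slope = np.polyfit(d["x"], d["y"], 1)[0]
        assert beta == pytest.approx(ols_slope, rel=0.02)

    def test_clustered_fit_coverage_on_hierarchical_data(self):
        from betaforest import simulate

        cover = 0
        for seed in range(100):
            cfg = simulate.HierarchyConfig(
                n_countries=20,
                schools_per_country=10,
                students_per_school=10,
                true_slopes={"GDP": 0.25},
                seed=seed,
            )
            t = simulate.simulate_timss_like(cfg)
            f = fit_single_model(
                t, ModelSpec("BSMMAT01", "GDP", weight_name="weight", cluster_name="school_id")
            )
            cover += f.ci_lower <= 0.25 <= f.ci_upper
        assert cover >= 90


class TestFitModelGrid:
    def test_grid_250(self, timss_fit_table):
        assert len(timss_fit_table) == 250
        assert list(timss_fit_table.columns) == FIT_TABLE_COLUMNS

    def test_grid_70(self, decathlon_small):
        from betaforest.simulate import EVENT_NAMES, MARKER_NAMES

        fits = fit_model_grid(decathlon_small, EVENT_NAMES, MARKER_NAMES)
        assert len(fits) == 70
        assert (fits["error"] == "").all()

    def test_grid_of_one_equals_single_fit(self):
        d = make_bivariate(0.2, 60, 1)
        grid = fit_model_grid(d, ["y"], ["x"])
        single = fit_single_model(d, ModelSpec("y", "x"))
        assert len(grid) == 1
        assert grid.loc[0, "beta"] == pytest.approx(single.beta, abs=1e-12)
        assert grid.loc[0, "se"] == pytest.approx(single.se, abs=1e-12)

    def test_row_order_predictor_outer(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(rng.standard_normal((30, 4)), columns=["o1", "o2", "p1", "p2"])
        grid = fit_model_grid(d, ["o1", "o2"], ["p1", "p2"])
        assert list(zip(grid["predictor"], grid["outcome"])) == [
            ("p1", "o1"),
            ("p1", "o2"),
            ("p2", "o1"),
            ("p2", "o2"),
        ]

    def test_failed_cell_is_error_note_not_exception(self):
        d = pd.DataFrame({"o": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0], "p": [1.0, 3.0, 2.0]})
        grid = fit_model_grid(d, ["o", "c"], ["p"])
        assert len(grid) == 2
        assert grid.loc[grid["outcome"] == "c", "error"].str.contains("zero-variance").all()
        assert (grid.loc[grid["outcome"] == "o", "error"] == "").all()

    def test_empty_lists_error(self):
        d = make_bivariate(0.1, 30, 0)
        with pytest.raises(ValueError):
            fit_model_grid(d, [], ["x"])
        with pytest.raises(ValueError, match="overlap"):
            fit_model_grid(d, ["y"], ["y"])
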