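import numpy as np
import pytest

from biolube.design import map_levels
from biolube.synthetic_data import GeneratorConfig, generate_experiment
from biolube.variance_model import (
    ExtrapolationWarning,
    LinearModel,
    contour_grid,
    fit_linear_model,
    ols_slope_closed_form,
    parity_data,
    predict_conversion,
    taguchi_anova,
)

# Factor sums of squares for the bundled dataset, frozen from a direct
# level-mean computation (oracle re-derived in test_ss_against_brute_force).
EXPECTED_SS = {"MR": 369.6822, "Cat": 156.9756, "BL": 497.8956, "t": 33.1022}
EXPECTED_SS_TOTAL = 1057.6556


def _model_with_published_coefficients():
    return LinearModel(
        factor_names=("MR", "Cat", "BL", "t"),
        intercept=100.7,
        coefficients={"MR": -1.878, "Cat": -0.409, "BL": -0.299, "t": 0.04},
        residuals=np.zeros(9),
        r_squared=1.0,
        design_ranges={"MR": (1, 9), "Cat": (5, 15), "BL": (20, 80), "t": (48, 96)},
    )


class TestTaguchiAnova:
    def test_ss_against_brute_force(self, l9, conversions):
        # oracle: explicit level-mean arithmetic, independent of the module
        y = np.asarray(conversions)
        grand = y.mean()
        table = taguchi_anova(l9, conversions)
        for j, name in enumerate(l9.factor_names):
            expected = 3 * sum(
                (y[l9.levels[:, j] == k].mean() - grand) ** 2 for k in (1, 2, 3)
            )
            row = [r for r in table.rows if r.name == name][0]
            assert row.ss == pytest.approx(expected, rel=1e-12)
            assert row.ss == pytest.approx(EXPECTED_SS[name], abs=5e-4)

    def test_total_ss_frozen_value(self, l9, conversions):
        table = taguchi_anova(l9, conversions)
        assert table.total_ss == pytest.approx(EXPECTED_SS_TOTAL, abs=5e-4)

    def test_decomposition_identity(self, l9, conversions):
        table = taguchi_anova(l9, conversions)
        assert sum(r.ss for r in table.rows) == pytest.approx(
            table.total_ss, rel=1e-6
        )

    def test_pools_smallest_ss_factor(self, l9, conversions):
        table = taguchi_anova(l9, conversions)
        assert table.pooled_factors == ["t"]
        assert table.error_df == 2
        assert table.error_ss == pytest.approx(EXPECTED_SS["t"], abs=5e-4)

    def test_contributions_sum_to_100(self, l9, conversions):
        table = taguchi_anova(l9, conversions)
        total = sum(r.contribution for r in table.rows if not r.pooled)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_f_and_p_consistency(self, l9, conversions):
        from scipy import stats

        table = taguchi_anova(l9, conversions)
        for row in table.rows:
            if row.pooled:
                assert row.f is None and row.p is None
                continue
            assert row.f == pytest.approx(row.ms / table.error_ms)
            assert row.p == pytest.approx(stats.f.sf(row.f, 2, table.error_df))
            assert 0 <= row.p <= 1

    def test_df_bookkeeping(self, l9, conversions):
        table = taguchi_anova(l9, conversions)
        assert all(r.df == 2 for r in table.rows)
        assert table.total_df == 8

    def test_constant_responses_degenerate(self, l9):
        table = taguchi_anova(l9, [70.0] * 9)
        assert table.degenerate
        assert all(r.ss == pytest.approx(0.0) for r in table.rows)
        assert all(r.contribution == 0.0 for r in table.rows if not r.pooled)

    def test_unbalanced_design_rejected(self, l9, conversions):
        l9.levels[0, 0] = 2
        with pytest.raises(ValueError, match="not balanced"):
            taguchi_anova(l9, conversions)

    def test_pooling_everything_rejected(self, l9, conversions):
        with pytest.raises(ValueError, match="pool all"):
            taguchi_anova(l9, conversions, n_pool=4)


class TestFitLinearModel:
    def test_study_fit_against_normal_equations_oracle(self, physical, conversions):
        model = fit_linear_model(physical, conversions)
        X = np.column_stack(
            [np.ones(9)] + [physical[c].to_numpy(float) for c in ("MR", "Cat", "BL", "t")]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(conversions))
        assert model.intercept == pytest.approx(beta[0], rel=1e-9)
        for i, f in enumerate(("MR", "Cat", "BL", "t")):
            assert model.coefficients[f] == pytest.approx(beta[i + 1], rel=1e-9)

    def test_study_fit_frozen_coefficients(self, physical, conversions):
        model = fit_linear_model(physical, conversions)
        assert model.intercept == pytest.approx(100.7903, abs=5e-4)
        assert model.coefficients["MR"] == pytest.approx(-1.8792, abs=5e-4)
        assert model.coefficients["Cat"] == pytest.approx(-0.4100, abs=5e-4)
        assert model.coefficients["BL"] == pytest.approx(-0.2994, abs=5e-4)
        assert model.coefficients["t"] == pytest.approx(0.0389, abs=5e-4)
        assert 0 <= model.r_squared <= 1

    def test_slopes_match_balanced_closed_form(self, l9, factors, physical, conversions):
        model = fit_linear_model(physical, conversions)
        for spec in factors:
            closed = ols_slope_closed_form(l9, spec.name, spec, conversions)
            assert model.coefficients[spec.name] == pytest.approx(closed, rel=1e-9)

    def test_noiseless_synthetic_exact_recovery(self, l9, factors, physical):
        cfg = GeneratorConfig(
            beta0=90.0, betas={"MR": -1.5, "Cat": 0.3, "BL": -0.2, "t": 0.05}, seed=7
        )
        results, truth = generate_experiment(cfg, l9, factors)
        model = fit_linear_model(physical, [r.mean for r in results])
        assert model.intercept == pytest.approx(truth.beta0, abs=1e-8)
        for f, b in truth.betas.items():
            assert model.coefficients[f] == pytest.approx(b, abs=1e-8)

    def test_constant_responses_give_flat_model(self, physical):
        model = fit_linear_model(physical, [55.0] * 9)
        assert model.intercept == pytest.approx(55.0)
        for b in model.coefficients.values():
            assert b == pytest.approx(0.0, abs=1e-10)

    def test_residuals_sum_to_zero(self, physical, conversions):
        model = fit_linear_model(physical, conversions)
        assert model.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficiency_names_columns(self, physical, conversions):
        bad = physical.copy()
        bad["t"] = bad["BL"] * 2  # collinear with BL
        with pytest.raises(ValueError, match="rank deficient"):
            fit_linear_model(bad, conversions)

    def test_too_few_runs_rejected(self, physical, conversions):
        with pytest.raises(ValueError, match="at least 5"):
            fit_linear_model(physical.iloc[:4], conversions[:4])


class TestPredictConversion:
    def test_published_equation_hand_value(self):
        model = _model_with_published_coefficients()
        val, clamped = predict_conversion(
            model, {"MR": 5, "Cat": 10, "BL": 20, "t": 48}
        )
        # 100.7 - 9.39 - 4.09 - 5.98 + 1.92
        assert val == pytest.approx(83.16)
        assert not clamped

    def test_intercept_only_model(self):
        model = LinearModel(
            factor_names=("MR",), intercept=50.0, coefficients={"MR": 0.0},
            residuals=np.zeros(9), r_squared=0.0, design_ranges={"MR": (1, 9)},
        )
        assert predict_conversion(model, {"MR": 4})[0] == 50.0

    def test_clamp_flag(self):
        model = LinearModel(
            factor_names=("MR",), intercept=120.0, coefficients={"MR": 0.0},
            residuals=np.zeros(9), r_squared=0.0, design_ranges={"MR": (1, 9)},
        )
        val, clamped = predict_conversion(model, {"MR": 4})
        assert clamped and val == 100.0

    def test_extrapolation_warns(self):
        model = _model_with_published_coefficients()
        with pytest.warns(ExtrapolationWarning):
            predict_conversion(model, {"MR": 12, "Cat": 10, "BL": 50, "t": 72})

    def test_noiseless_model_reproduces_generator_anywhere(self, l9, factors, physical):
        cfg = GeneratorConfig(
            beta0=80.0, betas={"MR": -1.0, "Cat": 0.2, "BL": -0.1, "t": 0.01}, seed=3
        )
        results, _ = generate_experiment(cfg, l9, factors)
        model = fit_linear_model(physical, [r.mean for r in results])
        settings = {"MR": 3.0, "Cat": 7.5, "BL": 35.0, "t": 60.0}
        expected = 80.0 - 3.0 + 0.2 * 7.5 - 0.1 * 35.0 + 0.01 * 60.0
        assert predict_conversion(model, settings)[0] == pytest.approx(expected)


class TestContourGrid:
    def test_corner_values_match_predictions(self):
        model = _model_with_published_coefficients()
        fixed = {"MR": 5, "t": 48}
        cg = contour_grid(model, "BL", "Cat", fixed, resolution=2)
        for iy, cat in enumerate(cg.y_values):
            for ix, bl in enumerate(cg.x_values):
                expected, _ = predict_conversion(
                    model, {"MR": 5, "t": 48, "BL": bl, "Cat": cat}
                )
                assert cg.grid[iy, ix] == pytest.approx(expected)

    def test_monotone_along_negative_slope_axis(self):
        model = _model_with_published_coefficients()
        cg = contour_grid(model, "BL", "Cat", {"MR": 5, "t": 48}, resolution=5)
        assert (np.diff(cg.grid, axis=1) <= 1e-12).all()  # bC < 0

    def test_grid_node_count(self):
        model = _model_with_published_coefficients()
        cg = contour_grid(model, "BL", "Cat", {"MR": 5, "t": 48}, resolution=3)
        assert cg.grid.shape == (3, 3)

    def test_unknown_factor_rejected(self):
        model = _model_with_published_coefficients()
        with pytest.raises(ValueError, match="unknown factor"):
            contour_grid(model, "XX", "Cat", {}, resolution=3)

    def test_same_axis_rejected(self):
        model = _model_with_published_coefficients()
        with pytest.raises(ValueError):
            contour_grid(model, "BL", "BL", {}, resolution=3)


class TestParityData:
    def test_study_pairs_residuals_sum_to_zero(self, physical, conversions):
        model = fit_linear_model(physical, conversions)
        pairs, max_resid = parity_data(model, physical, conversions)
        assert len(pairs) == 9
        assert sum(o - p for o, p in pairs) == pytest.approx(0.0, abs=1e-9)
        assert max_resid >= 0

    def test_noiseless_pairs_on_diagonal(self, l9, factors, physical):
        cfg = GeneratorConfig(beta0=70.0, betas={"MR": 0.5, "Cat": 0.0, "BL": 0.1, "t": 0.0})
        results, _ = generate_experiment(cfg, l9, factors)
        ys = [r.mean for r in results]
        model = fit_linear_model(physical, ys)
        pairs, max_resid = parity_data(model, physical, ys)
        assert max_resid == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_rejected(self, physical, conversions):
        model = fit_linear_model(physical, conversions)
        with pytest.raises(ValueError):
            parity_data(model, physical, conversions[:5])
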