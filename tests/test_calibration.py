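"""Calibration equations, constrained least squares, and two-regression prediction."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from metcalib import (
    ActivityClass,
    CalibrationEquation,
    CutoffSpec,
    EpochFeatures,
    METRegression,
    SubjectCovariates,
    fit_fixed_intercept,
    fit_ols,
    goodness_of_fit,
    predict_met,
    two_regression_predict,
)
from metcalib.equations import (
    EQ1, EQ2, EQ3, EQ4, EQ5, EQ6, PUBLISHED_SEE, load_equation_set,
)
from metcalib.simulate import generate_calibration_sample


def _epoch(filtered, ratio):
    return EpochFeatures(0, 60.0, filtered, filtered * (ratio or 1.0), ratio=ratio)


class TestPredictMet:
    def test_fixed_intercept_at_zero_movement_is_0p9(self):
        """Motionless wakefulness is pinned at 0.9 METs."""
        assert predict_met(EQ2, 0.0) == pytest.approx(0.9)
        assert predict_met(EQ5, 0.0) == pytest.approx(0.9)

    def test_quadratic_equation_hand_arithmetic(self):
        # 0.0144*16.3 - 0.0000147*16.3^2 + 0.9
        assert predict_met(EQ5, 16.3) == pytest.approx(1.131, abs=5e-4)

    def test_ambulatory_equation_hand_arithmetic(self):
        # 1.0012 + 0.00370*838.9
        assert predict_met(EQ6, 838.9) == pytest.approx(4.105, abs=5e-4)

    def test_covariate_equation_requires_its_covariate(self):
        with pytest.raises(ValueError, match="sex"):
            predict_met(EQ3, 100.0)
        with pytest.raises(ValueError, match="age"):
            predict_met(EQ4, 100.0, SubjectCovariates(sex=1))
        assert predict_met(EQ3, 0.0, SubjectCovariates(sex=0)) == pytest.approx(0.9)
        assert predict_met(EQ3, 0.0, SubjectCovariates(sex=1)) == pytest.approx(1.118)

    def test_fixed_intercept_forms_validate_intercept(self):
        with pytest.raises(ValueError, match="0.9"):
            CalibrationEquation("linear_fixed_intercept", 1.0, 0.01)

    def test_negative_acceleration_rejected(self):
        with pytest.raises(ValueError):
            predict_met(EQ6, -1.0)


class TestTwoRegressionPredict:
    def test_ambulatory_branch(self):
        pred = two_regression_predict([_epoch(306.1, 1.00)], EQ5, EQ6)
        assert pred.mets[0] == pytest.approx(2.134, abs=5e-4)
        assert pred.classes[0] is ActivityClass.AMBULATORY

    def test_non_ambulatory_branch(self):
        pred = two_regression_predict([_epoch(102.3, 2.10)], EQ5, EQ6)
        assert pred.mets[0] == pytest.approx(2.219, abs=5e-4)
        assert pred.classes[0] is ActivityClass.NON_AMBULATORY

    def test_still_epoch_gets_fixed_intercept(self):
        pred = two_regression_predict([_epoch(0.0, None)], EQ5, EQ6)
        assert pred.mets[0] == pytest.approx(0.9)
        assert pred.classes[0] is ActivityClass.STILL

    def test_equation_class_mismatch_rejected(self):
        with pytest.raises(ValueError, match="non-ambulatory"):
            two_regression_predict([_epoch(1.0, 1.0)], EQ6, EQ6)
        with pytest.raises(ValueError, match="ambulatory"):
            two_regression_predict([_epoch(1.0, 1.0)], EQ5, EQ5)

    def test_no_nan_and_continuity_within_class(self):
        """Predictions are finite, and continuous in filtered_mg within a class."""
        grid = np.linspace(0.0, 1200.0, 4001)
        epochs = [_epoch(x, 1.0) for x in grid]
        mets = two_regression_predict(epochs, EQ5, EQ6).mets
        assert np.all(np.isfinite(mets))
        assert np.max(np.abs(np.diff(mets))) < 0.01  # small steps on a fine grid

    def test_negative_extrapolation_flagged_not_clamped(self):
        deep_neg = CalibrationEquation(
            "linear", -5.0, 0.001, target_class=ActivityClass.AMBULATORY
        )
        with pytest.warns(RuntimeWarning, match="negative"):
            pred = two_regression_predict([_epoch(10.0, 1.0)], EQ5, deep_neg)
        assert pred.mets[0] < 0 and pred.negative[0]


class TestFitOLS:
    def test_noiseless_recovery_of_ambulatory_equation(self):
        x = np.linspace(200, 900, 40)
        res = fit_ols(x, 1.0012 + 0.00370 * x)
        assert res.equation.intercept == pytest.approx(1.0012, abs=1e-10)
        assert res.equation.slope_counts == pytest.approx(0.00370, abs=1e-12)
        assert res.see == pytest.approx(0.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slope(self):
        x = np.linspace(0, 100, 20)
        res = fit_ols(x, np.full(20, 2.5))
        assert res.equation.slope_counts == pytest.approx(0.0, abs=1e-12)
        assert res.equation.intercept == pytest.approx(2.5)

    def test_noisy_slope_recovery_within_3_se(self):
        x, _, y = generate_calibration_sample(EQ1, PUBLISHED_SEE[EQ1], 500, (5, 300), seed=42)
        res = fit_ols(x, y)
        slope_idx = res.param_names.index("filtered_mg")
        assert abs(res.params[slope_idx] - 0.0087) < 3 * res.bse[slope_idx]

    def test_agrees_with_closed_form_on_random_small_instances(self, rng):
        """Slope/intercept match the textbook formulas to 1e-10."""
        for _ in range(20):
            n = rng.integers(3, 11)
            x = rng.uniform(0, 300, n)
            if np.ptp(x) < 1e-6:
                continue
            y = rng.uniform(0.9, 5.0, n)
            res = fit_ols(x, y)
            sxy = np.sum((x - x.mean()) * (y - y.mean()))
            sxx = np.sum((x - x.mean()) ** 2)
            assert res.equation.slope_counts == pytest.approx(sxy / sxx, abs=1e-10)
            assert res.equation.intercept == pytest.approx(
                y.mean() - sxy / sxx * x.mean(), abs=1e-10
            )

    def test_agrees_with_statsmodels(self, rng):
        x = rng.uniform(5, 300, 80)
        y = 1.2 + 0.009 * x + rng.normal(0, 0.4, 80)
        res = fit_ols(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(res.params, ref.params, atol=1e-10)
        np.testing.assert_allclose(res.bse, ref.bse, atol=1e-10)
        assert res.rsquared == pytest.approx(ref.rsquared, abs=1e-12)

    def test_degenerate_x_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(np.full(10, 5.0), np.arange(10.0))


class TestFitFixedIntercept:
    def test_noiseless_quadratic_recovery(self):
        x = np.linspace(5, 300, 60)
        y = 0.9 + 0.0144 * x - 0.0000147 * x**2
        res = fit_fixed_intercept(np.column_stack([x, x**2]), y)
        np.testing.assert_allclose(res.params, [0.0144, -0.0000147], atol=1e-12)

    def test_single_point_through_origin_solution(self):
        """(1.93 - 0.9)/100 = 0.0103, the published non-ambulatory slope."""
        x = np.array([100.0, 100.0, 200.0])
        y = 0.9 + 0.0103 * x
        res = fit_fixed_intercept(x.reshape(-1, 1), y)
        assert res.params[0] == pytest.approx(0.0103, abs=1e-12)
        assert (1.93 - 0.9) / 100 == pytest.approx(0.0103)

    def test_noisy_quadratic_leading_coefficient_within_3_se(self):
        x, _, y = generate_calibration_sample(EQ5, PUBLISHED_SEE[EQ5], 500, (5, 300), seed=11)
        res = fit_fixed_intercept(np.column_stack([x, x**2]), y)
        assert abs(res.params[0] - 0.0144) < 3 * res.bse[0]

    def test_covariate_form_recovers_coefficients(self):
        x, cov, y = generate_calibration_sample(
            EQ3, 0.0, 60, (5, 300), covariate_values=[0, 1], seed=5
        )
        res = fit_fixed_intercept(
            np.column_stack([x, cov]), y, covariate_name="sex"
        )
        np.testing.assert_allclose(res.params, [0.0089, 0.2180], atol=1e-10)
        assert res.equation.covariate_name == "sex"

    def test_matches_normal_equation_oracle(self, rng):
        """Constrained fit == normal equations on (y - 0.9) through the origin."""
        x = rng.uniform(5, 300, 100)
        y = 0.9 + 0.012 * x - 1e-5 * x**2 + rng.normal(0, 0.3, 100)
        X = np.column_stack([x, x**2])
        res = fit_fixed_intercept(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ (y - 0.9))
        np.testing.assert_allclose(res.params, oracle, atol=1e-8)

    def test_matches_statsmodels_through_origin(self, rng):
        x = rng.uniform(5, 300, 100)
        y = 0.9 + 0.01 * x + rng.normal(0, 0.3, 100)
        res = fit_fixed_intercept(x.reshape(-1, 1), y)
        ref = sm.OLS(y - 0.9, x).fit()
        assert res.params[0] == pytest.approx(ref.params[0], abs=1e-12)
        assert res.rsquared_uncentered == pytest.approx(ref.rsquared, abs=1e-10)

    def test_rank_deficient_design_raises(self):
        x = np.linspace(1, 10, 20)
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            fit_fixed_intercept(np.column_stack([x, 2 * x]), np.ones(20), covariate_name="sex")


class TestModelInterface:
    def test_stair_labels_excluded_by_default(self):
        x = np.array([300.0, 310.0, 250.0, 320.0, 840.0, 305.0])
        y = 1.0012 + 0.00370 * x
        labels = [
            "normal walking", "brisk walking", "ascending stairs",
            "normal walking", "jogging", "descending stairs",
        ]
        y = y.copy()
        y[2] = 4.03  # stairs sit far off the ambulatory line
        y[5] = 2.00
        res = METRegression(y, x, form="linear", labels=labels).fit()
        assert res.excluded_labels == ["ascending stairs", "descending stairs"]
        assert res.nobs == 4
        assert res.equation.slope_counts == pytest.approx(0.00370, abs=1e-10)

    def test_summary_reports_fit_quality(self):
        x = np.linspace(5, 300, 30)
        res = METRegression(0.9 + 0.0103 * x, x, form="linear_fixed_intercept").fit()
        text = res.summary()
        assert "SEE" in text and "0.0103" in text and "(fixed)" in text

    def test_centered_vs_uncentered_rsquared_ordering(self, rng):
        """Uncentered R2 >= centered R2 for a through-origin fit of y - 0.9."""
        x = rng.uniform(5, 300, 200)
        y = 0.9 + 0.0103 * x + rng.normal(0, 0.4, 200)
        res = METRegression(y, x, form="linear_fixed_intercept").fit()
        assert res.rsquared_uncentered >= res.rsquared


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        out = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 2)
        assert out["see"] == 0.0 and out["r_squared"] == 1.0

    def test_mean_prediction_gives_zero_rsquared(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = goodness_of_fit(np.full(4, y.mean()), y, 1)
        assert out["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        y = rng.uniform(1, 5, 30)
        yp = y + rng.normal(0, 0.3, 30)
        out = goodness_of_fit(yp, y, 2)
        sse = np.sum((y - yp) ** 2)
        assert out["see"] == pytest.approx(np.sqrt(sse / 28), abs=1e-12)
        assert out["r_squared"] == pytest.approx(
            1 - sse / np.sum((y - y.mean()) ** 2), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0], [1.0], 0)


class TestEquationSetIO:
    def test_bundled_young_children_set(self):
        nonamb, amb, pop = load_equation_set()
        assert pop == "young_children"
        assert nonamb.form == "quadratic_fixed_intercept"
        assert nonamb.predict(0.0) == pytest.approx(0.9)
        assert amb.predict(306.1) == pytest.approx(2.134, abs=5e-4)

    def test_round_trip_through_dict(self):
        for eq in (EQ1, EQ2, EQ5, EQ6):
            again = CalibrationEquation.from_dict(
                eq.to_dict(), eq.target_class, eq.population_tag
            )
            assert again == eq


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    slope=st.floats(min_value=0.001, max_value=0.02),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_noiseless_fixed_intercept_recovery_property(slope, seed):
    """Any through-origin linear law at intercept 0.9 is recovered exactly."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(5, 300, 30)
    res = fit_fixed_intercept(x.reshape(-1, 1), 0.9 + slope * x)
    assert res.params[0] == pytest.approx(slope, rel=1e-9)
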