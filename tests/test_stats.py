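"""Unit and property tests for the agreement-statistics engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from wearvalid import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
    cv_confidence_limits,
    cv_from_tee,
    fisher_confidence_limits,
    fit_criterion_regression,
    log_transform,
    pearson_with_limits,
    standardized_mean_bias,
    stee_from_r,
    summarize_condition,
    tee_from_cv,
)
from wearvalid.simulate import generate_cohort, uniform_truth


class TestLogTransform:
    def test_analytic_points(self):
        assert log_transform([1.0])[0] == 0.0
        assert log_transform([math.e])[0] == pytest.approx(100.0, abs=1e-12)

    @pytest.mark.parametrize("x", [68.8, 0.5, 7.6, 177.0])
    def test_matches_high_precision_log(self, x):
        # oracle: direct evaluation of 100·ln with the math library
        assert log_transform([x])[0] == pytest.approx(100.0 * math.log(x), rel=1e-14)

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.nan, math.inf])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValidationError):
            log_transform([1.0, bad])


def _normal_equations_oracle(x, y):
    """Brute-force least squares via the closed-form normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    tee = math.sqrt((resid * resid).sum() / (n - 2))
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * (y * y).sum() - sy * sy))
    return slope, intercept, tee, r


class TestCriterionRegression:
    def test_collinear_points_have_zero_tee(self):
        x = np.arange(5.0)
        fit = fit_criterion_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.tee_log == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.r_log) == pytest.approx(1.0)

    def test_small_example_matches_normal_equations(self):
        x = np.array([0.0, 100.0, 200.0])
        y = np.array([0.0, 90.0, 210.0])
        fit = fit_criterion_regression(x, y)
        slope, intercept, tee, r = _normal_equations_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.tee_log == pytest.approx(tee, rel=1e-12)
        assert fit.r_log == pytest.approx(r, rel=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 7, 10])
    def test_random_datasets_match_oracle(self, n, rng):
        for _ in range(20):
            x = rng.normal(400, 20, n)
            y = 0.8 * x + rng.normal(0, 5, n) + 40
            fit = fit_criterion_regression(x, y)
            slope, intercept, tee, r = _normal_equations_oracle(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.tee_log == pytest.approx(tee, rel=1e-10)
            assert fit.r_log == pytest.approx(r, rel=1e-10)

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            fit_criterion_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            fit_criterion_regression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestStee:
    def test_printed_pairing(self):
        # the r/sTEE pairing a validity table prints: r 0.85 ↔ sTEE 0.62
        assert round(stee_from_r(0.85), 2) == 0.62

    def test_analytic_points(self):
        assert stee_from_r(1.0) == 0.0
        assert stee_from_r(1 / math.sqrt(2)) == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(0.05, 0.999))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_strictly_decreasing_in_abs_r(self, r):
        assert stee_from_r(r) > stee_from_r(min(r + 1e-3, 1.0))
        assert stee_from_r(-r) == stee_from_r(r)

    def test_undefined_at_zero(self):
        with pytest.raises(DegenerateInputError):
            stee_from_r(0.0)


class TestCvBackTransform:
    def test_analytic_points(self):
        assert cv_from_tee(0.0) == 0.0
        assert cv_from_tee(100.0 * math.log(1.05)) == pytest.approx(5.0, rel=1e-12)
        # oracle: direct exponential evaluation
        assert cv_from_tee(20.0) == pytest.approx(100 * (math.exp(0.2) - 1), rel=1e-12)

    def test_inverse_roundtrip(self):
        for cv in (0.5, 2.0, 19.1, 34.5):
            assert cv_from_tee(tee_from_cv(cv)) == pytest.approx(cv, rel=1e-12)

    @given(st.floats(0.01, 5.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_small_error_linearization(self, s):
        # within 3% of the identity for log-scale SDs up to 5
        assert abs(cv_from_tee(s) - s) / s < 0.03

    @given(st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_increasing_and_convex(self, s):
        h = 0.1
        f0, f1, f2 = cv_from_tee(s), cv_from_tee(s + h), cv_from_tee(s + 2 * h)
        assert f1 > f0
        assert f2 - f1 >= f1 - f0  # convexity

    def test_rejects_negative(self):
        with pytest.raises(ValidationError):
            cv_from_tee(-0.1)


class TestCvConfidenceLimits:
    def test_study_sized_interval(self):
        # oracle: chi-square quantile computation; a 2% CV at n = 25
        tee = tee_from_cv(2.0)
        lo, hi = cv_confidence_limits(tee, 25)
        df = 23
        lo_o = cv_from_tee(tee * math.sqrt(df / sps.chi2.ppf(0.95, df)))
        hi_o = cv_from_tee(tee * math.sqrt(df / sps.chi2.ppf(0.05, df)))
        assert (lo, hi) == pytest.approx((lo_o, hi_o), rel=1e-12)
        assert round(lo, 1) == 1.6
        assert hi == pytest.approx(2.66, abs=0.01)
        assert lo <= 2.0 <= hi

    def test_interval_shrinks_with_n(self):
        tee = tee_from_cv(5.0)
        widths = [np.diff(cv_confidence_limits(tee, n))[0] for n in (10, 100, 10_000)]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 0.25

    def test_empirical_coverage_at_study_size(self, rng):
        """90% chi-square limits cover the true CV in ~90% of replicates."""
        n, sigma, reps = 25, 5.0, 2000
        true_cv = cv_from_tee(sigma)
        covered = 0
        x = rng.normal(450, 20, n)  # fixed predictor across replicates
        for _ in range(reps):
            y = 10 + 0.9 * x + rng.normal(0, sigma, n)
            fit = fit_criterion_regression(x, y)
            lo, hi = cv_confidence_limits(fit.tee_log, n)
            covered += lo <= true_cv <= hi
        assert covered / reps == pytest.approx(0.90, abs=0.03)


class TestPearsonWithLimits:
    def test_perfect_correlation_collapses(self):
        x = np.arange(10.0) + 1
        est = pearson_with_limits(x, 2 * x)
        assert (est.value, est.lower, est.upper) == (1.0, 1.0, 1.0)

    def test_matches_independent_fisher_arithmetic(self, rng):
        # oracle: scipy's own Fisher-z interval on the same data
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        est = pearson_with_limits(x, y, level=0.90)
        res = sps.pearsonr(x, y)
        ci = res.confidence_interval(confidence_level=0.90)
        assert est.value == pytest.approx(res.statistic, rel=1e-12)
        assert est.lower == pytest.approx(ci.low, rel=1e-9)
        assert est.upper == pytest.approx(ci.high, rel=1e-9)

    @pytest.mark.parametrize("r", [-0.9, -0.3, 0.2, 0.7, 0.99])
    def test_limits_bracket_r_and_collapse_with_n(self, r):
        lo1, hi1 = fisher_confidence_limits(r, 20)
        lo2, hi2 = fisher_confidence_limits(r, 20_000)
        assert lo1 < r < hi1
        assert lo2 < r < hi2
        assert hi2 - lo2 < (hi1 - lo1) / 10

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_limits([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(InsufficientDataError):
            pearson_with_limits([1, 2, 3], [1, 2, 3])


class TestStandardizedMeanBias:
    def test_identical_measurements_give_zero(self):
        y = np.array([400.0, 420.0, 450.0, 480.0])
        est = standardized_mean_bias(y, y)
        assert (est.value, est.lower, est.upper) == (0.0, 0.0, 0.0)

    def test_unit_shift(self):
        y = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        c = float(np.std(y, ddof=1))
        est = standardized_mean_bias(y + c, y)
        assert est.value == pytest.approx(1.0, rel=1e-12)

    def test_matches_step_by_step_arithmetic(self, rng):
        # oracle: spreadsheet-style two-step computation
        y = rng.normal(430, 15, 25)
        x = y + rng.normal(2, 4, 25)
        est = standardized_mean_bias(x, y, level=0.90)
        d = x - y
        sd_c = np.std(y, ddof=1)
        half = sps.t.ppf(0.95, 24) * np.std(d, ddof=1) / math.sqrt(25)
        assert est.value == pytest.approx(d.mean() / sd_c, rel=1e-12)
        assert est.lower == pytest.approx((d.mean() - half) / sd_c, rel=1e-12)
        assert est.upper == pytest.approx((d.mean() + half) / sd_c, rel=1e-12)

    def test_constant_criterion_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardized_mean_bias([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestSummarizeCondition:
    def test_perfect_agreement_is_exactly_zero_error(self, identity_cohort):
        crit, dev = identity_cohort.pairs("perfect", "sitting")
        s = summarize_condition(crit, dev, device_id="perfect", condition_id="sitting")
        assert s.cv_pct.value == 0.0
        assert s.stee.value == 0.0
        assert s.std_mean_bias.value == 0.0
        assert s.pearson_r.value == 1.0
        assert s.flags == ()

    def test_recovers_5pct_error_cv_at_large_n(self):
        truth = uniform_truth(
            "hr", devices=("dev",), error_cv_pct=5.0, n_participants=1000, seed=3
        )
        cohort = generate_cohort(truth)
        crit, dev = cohort.pairs("dev", "sitting")
        s = summarize_condition(crit, dev)
        assert 4.5 <= s.cv_pct.value <= 5.5

    def test_minimum_pairs_enforced(self):
        with pytest.raises(InsufficientDataError):
            summarize_condition([70, 71, 72], [70, 72, 71])
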