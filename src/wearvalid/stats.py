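"""Method-comparison statistics for device-vs-criterion validity.

The engine implements the agreement workflow used in sports-science
validation studies of wearable monitors:

1. log-transform both measures as ``100·ln(x)`` so that multiplicative
   (percent-type) error becomes additive and log-scale SDs read as
   approximate CV percentages;
2. regress the criterion on the device reading; the residual SD with
   n−2 degrees of freedom is the typical error of the estimate (TEE) —
   the expected error when inferring the true value from the wearable;
3. standardize: sTEE = sqrt(1/r² − 1) from the log-scale correlation
   (equivalently, TEE divided by the SD of the predicted criterion);
4. back-transform the TEE into a coefficient of variation,
   CV% = 100·(exp(TEE/100) − 1);
5. attach 90% confidence limits: chi-square (n−2 df) for TEE/CV,
   Fisher z with SE 1/sqrt(n−3) for r, Student t (n−1 df) for the
   standardized mean bias.

:func:`summarize_condition` composes the steps for one device×condition
cell; :func:`analyze_cohort` maps it over a :class:`~wearvalid.datamodel.Cohort`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .datamodel import Cohort, Estimate, RegressionFit, ValiditySummary
from .exceptions import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "log_transform",
    "fit_criterion_regression",
    "stee_from_r",
    "cv_from_tee",
    "tee_from_cv",
    "cv_confidence_limits",
    "fisher_confidence_limits",
    "pearson_with_limits",
    "standardized_mean_bias",
    "summarize_condition",
    "analyze_cohort",
]


def log_transform(values) -> np.ndarray:
    """Return ``100·ln(x)`` elementwise.

    The factor 100 makes log-scale standard deviations directly
    interpretable as approximate coefficients of variation in percent.
    Raises :class:`ValidationError` for non-positive or non-finite input.
    """
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError("log_transform requires strictly positive finite values")
    return 100.0 * np.log(arr)


def fit_criterion_regression(device_log, criterion_log) -> RegressionFit:
    """Least-squares fit of criterion (response) on device (predictor).

    Both vectors are expected on the 100·ln scale.  The typical error of
    the estimate is the residual SD with n−2 degrees of freedom; ``r_log``
    is the Pearson correlation of the two vectors.
    """
    x = np.asarray(device_log, dtype=float)
    y = np.asarray(criterion_log, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("device_log and criterion_log must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3, got n = {n}")
    if np.allclose(x, x[0]):
        raise DegenerateInputError("device values are constant; slope undefined")
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rss = float(resid @ resid)
    # Exactly collinear data leave only rounding noise in the residuals;
    # clamp so that a perfect fit reports tee = 0 and |r| = 1 exactly.
    if rss <= float(y @ y) * 1e-28:
        rss = 0.0
    r = float(fit.rvalue)
    if 1.0 - abs(r) < 1e-14:
        r = math.copysign(1.0, r)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        tee_log=math.sqrt(rss / (n - 2)),
        r_log=r,
        n=n,
    )


def stee_from_r(r_log: float) -> float:
    """Standardized typical error of the estimate from a correlation.

    sTEE = sqrt(1/r² − 1); strictly decreasing in |r|, zero at |r| = 1.
    Undefined at r = 0 (raises :class:`DegenerateInputError`; the summary
    layer reports NaN with a flag instead).
    """
    if not math.isfinite(r_log) or abs(r_log) > 1:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r_log}")
    if r_log == 0:
        raise DegenerateInputError("sTEE undefined for r = 0")
    return math.sqrt(1.0 / (r_log * r_log) - 1.0)


def cv_from_tee(tee_log: float) -> float:
    """Back-transform a 100·ln-scale error SD to a CV in percent.

    CV% = 100·(exp(tee/100) − 1); ≈ tee_log itself for small errors.
    """
    if not math.isfinite(tee_log) or tee_log < 0:
        raise ValidationError(f"tee_log must be >= 0, got {tee_log}")
    return 100.0 * math.expm1(tee_log / 100.0)


def tee_from_cv(cv_pct: float) -> float:
    """Inverse of :func:`cv_from_tee`: 100·ln(1 + CV/100)."""
    if not math.isfinite(cv_pct) or cv_pct < 0:
        raise ValidationError(f"cv_pct must be >= 0, got {cv_pct}")
    return 100.0 * math.log1p(cv_pct / 100.0)


def cv_confidence_limits(
    tee_log: float, n: int, level: float = 0.90
) -> tuple[float, float]:
    """Confidence limits for the CV, via chi-square on the residual variance.

    The residual sum of squares of a normal linear regression is
    σ²·χ²(n−2), so limits for the TEE are ``tee·sqrt(df/χ²_q)`` at the
    (1±level)/2 quantiles; each limit is then back-transformed to CV%.
    """
    if n < 3:
        raise InsufficientDataError(f"confidence limits need n >= 3, got n = {n}")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if tee_log < 0:
        raise ValidationError(f"tee_log must be >= 0, got {tee_log}")
    df = n - 2
    lo = tee_log * math.sqrt(df / sps.chi2.ppf((1 + level) / 2, df))
    hi = tee_log * math.sqrt(df / sps.chi2.ppf((1 - level) / 2, df))
    return cv_from_tee(lo), cv_from_tee(hi)


def fisher_confidence_limits(
    r: float, n: int, level: float = 0.90
) -> tuple[float, float]:
    """Fisher-z confidence limits for a Pearson correlation.

    z = atanh(r) is treated as normal with SE 1/sqrt(n−3).  At |r| = 1 the
    limits collapse to r (a perfect correlation has no sampling spread
    under this model).
    """
    if n < 4:
        raise InsufficientDataError(f"Fisher limits need n >= 4, got n = {n}")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if abs(r) > 1:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) >= 1.0 - 1e-15:
        return r, r
    z = math.atanh(r)
    half = sps.norm.ppf((1 + level) / 2) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def pearson_with_limits(x, y, level: float = 0.90) -> Estimate:
    """Sample Pearson correlation with Fisher-z confidence limits."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.shape != ya.shape:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = xa.size
    if n < 4:
        raise InsufficientDataError(f"correlation limits need n >= 4, got n = {n}")
    if np.allclose(xa, xa[0]) or np.allclose(ya, ya[0]):
        raise DegenerateInputError("correlation undefined for a constant vector")
    r = float(sps.pearsonr(xa, ya).statistic)
    if 1.0 - abs(r) < 1e-14:  # numerically perfect collinearity
        r = math.copysign(1.0, r)
    lo, hi = fisher_confidence_limits(r, n, level)
    return Estimate(r, lo, hi)


def standardized_mean_bias(device_log, criterion_log, level: float = 0.90) -> Estimate:
    """Mean device−criterion difference standardized by the criterion SD.

    Both vectors on the 100·ln scale.  Limits come from the Student-t
    interval (n−1 df) for the mean difference, divided by the same
    between-subject criterion SD.
    """
    x = np.asarray(device_log, dtype=float)
    y = np.asarray(criterion_log, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("paired vectors must be equal-length 1-D")
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"mean bias needs n >= 2, got n = {n}")
    sd_c = float(np.std(y, ddof=1))
    if sd_c == 0:
        raise DegenerateInputError("criterion is constant; standardization undefined")
    d = x - y
    mean_d = float(np.mean(d))
    half = float(sps.t.ppf((1 + level) / 2, n - 1)) * float(np.std(d, ddof=1)) / math.sqrt(n)
    return Estimate(mean_d / sd_c, (mean_d - half) / sd_c, (mean_d + half) / sd_c)


def _stee_estimate(fit: RegressionFit, level: float) -> tuple[Estimate, list[str]]:
    """sTEE point value and limits mapped through the Fisher limits of r_log.

    sTEE is strictly decreasing in |r|, so the upper r limit gives the
    lower sTEE limit and vice versa.  If the r interval touches zero the
    corresponding sTEE limit is unbounded (reported as +inf, flagged).
    """
    if fit.r_log == 0:
        return Estimate(math.nan), ["stee_undefined_r_zero"]
    point = stee_from_r(fit.r_log)
    # Limits for |r| (atanh is odd, so the |r| interval is the mirrored one).
    a = abs(fit.r_log)
    if a >= 1.0 - 1e-15:
        return Estimate(point, point, point), []
    r_lo, r_hi = fisher_confidence_limits(a, fit.n, level)
    lower = stee_from_r(r_hi)
    if r_lo <= 0:
        return Estimate(point, lower, math.inf), ["stee_cl_unbounded"]
    return Estimate(point, lower, stee_from_r(r_lo)), []


def summarize_condition(
    criterion,
    device,
    *,
    device_id: str = "",
    condition_id: str = "",
    level: float = 0.90,
) -> ValiditySummary:
    """Full validity block for one device×condition cell.

    Composes log transform → regression TEE → sTEE, CV with chi-square
    limits, raw-scale Pearson r with Fisher limits, and the standardized
    mean bias.  The reported r is computed on the original scale; the sTEE
    comes from the log-scale correlation.
    """
    crit = np.asarray(criterion, dtype=float)
    dev = np.asarray(device, dtype=float)
    if crit.ndim != 1 or crit.shape != dev.shape:
        raise ValidationError("criterion and device must be equal-length 1-D vectors")
    n = crit.size
    if n < 4:
        raise InsufficientDataError(f"summary needs n >= 4 complete pairs, got {n}")

    crit_log = log_transform(crit)
    dev_log = log_transform(dev)
    fit = fit_criterion_regression(dev_log, crit_log)

    cv_point = cv_from_tee(fit.tee_log)
    cv_lo, cv_hi = cv_confidence_limits(fit.tee_log, n, level)
    stee, flags = _stee_estimate(fit, level)
    pearson = pearson_with_limits(dev, crit, level)
    bias = standardized_mean_bias(dev_log, crit_log, level)

    return ValiditySummary(
        device_id=device_id,
        condition_id=condition_id,
        n=n,
        criterion_mean=float(np.mean(crit)),
        criterion_sd=float(np.std(crit, ddof=1)),
        std_mean_bias=bias,
        pearson_r=pearson,
        cv_pct=Estimate(cv_point, cv_lo, cv_hi),
        stee=stee,
        flags=tuple(flags),
    )


def analyze_cohort(
    cohort: Cohort, level: float = 0.90, min_n: int = 4
) -> list[ValiditySummary]:
    """Summaries for every device×condition cell with at least ``min_n`` pairs.

    Cells with fewer pairs are skipped (the study design yields 25 pairs
    per cell; an undersized cell indicates missing data, handled pairwise).
    """
    out: list[ValiditySummary] = []
    for device_id in cohort.devices():
        for condition_id in cohort.conditions():
            crit, dev = cohort.pairs(device_id, condition_id)
            if crit.size < min_n:
                continue
            out.append(
                summarize_condition(
                    crit, dev, device_id=device_id, condition_id=condition_id, level=level
                )
            )
    return out
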