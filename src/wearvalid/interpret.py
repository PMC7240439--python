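"""Qualitative ratings, MET classification, derived errors, and reports.

Validity magnitudes are rated on ordered scales: the sTEE on half the
thresholds of a modified Cohen scale, Pearson r on a correlation scale that
starts at 0.45 (values below it are rendered "-"), and activity intensity
on the MET convention (< 3 light, < 6 moderate, otherwise vigorous).
Classification always operates on unrounded values; rounding belongs to
report rendering only.

The module also derives the quantities a reader can compute from a
validity table alone: absolute errors (CV × criterion mean), their
per-device averages over condition subsets, hourly energy-expenditure
errors, and the unweighted cross-condition average row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean

from .datamodel import Estimate, ValiditySummary
from .exceptions import ValidationError

__all__ = [
    "InterpretationScale",
    "MetResult",
    "STEE_SCALE",
    "PEARSON_SCALE",
    "MET_SCALE",
    "BELOW_SCALE_LABEL",
    "classify_stee",
    "classify_pearson",
    "met_value",
    "absolute_error",
    "aggregate_conditions",
    "subset_error_summary",
    "hourly_ee_error",
    "render_report",
    "plot_stee",
]

BELOW_SCALE_LABEL = "-"


@dataclass(frozen=True)
class InterpretationScale:
    """Ordered, contiguous bins mapping a statistic's value to a label.

    Each bin is (lower, upper, label, include_upper); bins are lower-closed
    and upper-open unless ``include_upper`` is set.  Bins are checked in
    order, so a closed upper edge shadows the next bin's lower edge.
    """

    name: str
    bins: tuple[tuple[float, float, str, bool], ...]

    def classify(self, value: float) -> str:
        if not math.isfinite(value):
            if math.isinf(value) and value > 0:
                return self.bins[-1][2]
            raise ValidationError(f"cannot classify non-finite value {value!r}")
        for lo, hi, label, include_upper in self.bins:
            if lo <= value < hi or (include_upper and value == hi):
                return label
        raise ValidationError(
            f"{value!r} outside the domain of scale {self.name!r}"
        )


# Half the thresholds of the modified Cohen scale for standardized errors.
STEE_SCALE = InterpretationScale(
    "stee",
    (
        (0.0, 0.1, "trivial", False),
        (0.1, 0.3, "small", False),
        (0.3, 0.6, "moderate", False),
        (0.6, 1.0, "large", False),
        (1.0, 2.0, "very large", True),
        (2.0, math.inf, "extremely large", False),
    ),
)

# Correlation scale; below 0.45 the study assigns no rating (rendered "-").
PEARSON_SCALE = InterpretationScale(
    "pearson",
    (
        (-1.0, 0.45, BELOW_SCALE_LABEL, False),
        (0.45, 0.70, "very poor", False),
        (0.70, 0.85, "poor", False),
        (0.85, 0.95, "good", False),
        (0.95, 0.995, "very good", False),
        (0.995, 1.0, "excellent", True),
    ),
)

# MET intensity levels; exactly 6 MET falls in "vigorous" (>= rule).
MET_SCALE = InterpretationScale(
    "met",
    (
        (0.0, 3.0, "light", False),
        (3.0, 6.0, "moderate", False),
        (6.0, math.inf, "vigorous", False),
    ),
)


@dataclass(frozen=True)
class MetResult:
    """A MET value (kcal·kg⁻¹·h⁻¹) with its intensity level."""

    met: float
    level: str


def classify_stee(stee: float) -> str:
    """Rate an sTEE magnitude (trivial … extremely large)."""
    if stee < 0:
        raise ValidationError(f"sTEE must be >= 0, got {stee}")
    return STEE_SCALE.classify(stee)


def classify_pearson(r: float) -> str:
    """Rate a Pearson correlation; values below 0.45 map to "-"."""
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    return PEARSON_SCALE.classify(r)


def met_value(
    ee_per_bout: float, bout_minutes: float = 5.0, body_mass_kg: float = 70.1
) -> MetResult:
    """MET level of a bout: extrapolate criterion EE to one hour per kg body mass.

    MET = EE_per_bout · (60 / bout_minutes) / body_mass, with EE in kcal and
    1 MET ≈ 1 kcal·kg⁻¹·h⁻¹.
    """
    if ee_per_bout <= 0 or bout_minutes <= 0 or body_mass_kg <= 0:
        raise ValidationError("ee_per_bout, bout_minutes and body_mass_kg must be > 0")
    met = ee_per_bout * (60.0 / bout_minutes) / body_mass_kg
    return MetResult(met=met, level=MET_SCALE.classify(met))


def absolute_error(cv_pct: float, criterion_mean: float) -> float:
    """Absolute typical error in original units: CV/100 × criterion mean."""
    if cv_pct < 0:
        raise ValidationError(f"cv_pct must be >= 0, got {cv_pct}")
    if criterion_mean <= 0:
        raise ValidationError(f"criterion_mean must be > 0, got {criterion_mean}")
    return cv_pct / 100.0 * criterion_mean


def aggregate_conditions(summaries: list[ValiditySummary]) -> ValiditySummary:
    """Unweighted cross-condition average row for one device.

    Each statistic's point value is the arithmetic mean of the per-condition
    point values; the criterion mean is the mean of condition means.  No
    confidence limits are aggregated (left NaN).
    """
    if not summaries:
        raise ValidationError("aggregate_conditions needs at least one summary")
    devices = {s.device_id for s in summaries}
    if len(devices) > 1:
        raise ValidationError(f"summaries span multiple devices: {sorted(devices)}")
    return ValiditySummary(
        device_id=summaries[0].device_id,
        condition_id="average",
        n=sum(s.n for s in summaries),
        criterion_mean=fmean(s.criterion_mean for s in summaries),
        criterion_sd=math.nan,
        std_mean_bias=Estimate(fmean(s.std_mean_bias.value for s in summaries)),
        pearson_r=Estimate(fmean(s.pearson_r.value for s in summaries)),
        cv_pct=Estimate(fmean(s.cv_pct.value for s in summaries)),
        stee=Estimate(fmean(s.stee.value for s in summaries)),
        flags=tuple(sorted({f for s in summaries for f in s.flags})),
    )


def subset_error_summary(
    summaries: list[ValiditySummary], condition_ids
) -> float:
    """Mean absolute error over a subset of conditions (one device).

    Uses each condition's CV% and criterion mean; the result is in the
    measurement's original units (bpm or kcal per bout).
    """
    ids = list(condition_ids)
    if not ids:
        raise ValidationError("condition subset must be non-empty")
    by_cond = {s.condition_id: s for s in summaries}
    missing = [c for c in ids if c not in by_cond]
    if missing:
        raise LookupError(f"unknown condition id(s): {missing}")
    return fmean(
        absolute_error(by_cond[c].cv_pct.value, by_cond[c].criterion_mean) for c in ids
    )


def hourly_ee_error(
    summaries: list[ValiditySummary],
    grand_criterion_mean: float,
    bout_minutes: float = 5.0,
) -> float:
    """Hourly energy-expenditure error for one device, in kcal/h.

    Mean of the per-condition CVs (%), applied to the grand criterion mean
    per bout, extrapolated from the bout duration to one hour.
    """
    if bout_minutes <= 0:
        raise ValidationError(f"bout_minutes must be > 0, got {bout_minutes}")
    if not summaries:
        raise ValidationError("hourly_ee_error needs at least one summary")
    mean_cv = fmean(s.cv_pct.value for s in summaries)
    return mean_cv / 100.0 * grand_criterion_mean * (60.0 / bout_minutes)


# ---------------------------------------------------------------------------
# Report rendering


def _fmt(x: float, nd: int) -> str:
    if not math.isfinite(x):
        return "inf" if x > 0 else ("-inf" if x < 0 else "NA")
    return f"{x:.{nd}f}"


def _fmt_est(e: Estimate, nd: int) -> str:
    if math.isnan(e.lower) and math.isnan(e.upper):
        return _fmt(e.value, nd)
    return f"{_fmt(e.value, nd)} ({_fmt(e.lower, nd)} to {_fmt(e.upper, nd)})"


def _rate_r(r: float) -> str:
    return classify_pearson(r) if math.isfinite(r) else "NA"


def _rate_stee(s: float) -> str:
    return classify_stee(s) if not math.isnan(s) else "NA"


def summary_row(s: ValiditySummary) -> dict:
    """Flatten one summary into a rendering dict with report rounding
    (bias/r/sTEE to 2 dp, CV to 1 dp) and ratings from unrounded values."""
    return {
        "device": s.device_id,
        "condition": s.condition_id,
        "n": s.n,
        "criterion_mean_sd": f"{_fmt(s.criterion_mean, 1)} ({_fmt(s.criterion_sd, 1)})",
        "std_mean_bias": _fmt_est(s.std_mean_bias, 2),
        "pearson_r": _fmt_est(s.pearson_r, 2),
        "r_rating": _rate_r(s.pearson_r.value),
        "cv_pct": _fmt_est(s.cv_pct, 1),
        "stee": _fmt_est(s.stee, 2),
        "stee_rating": _rate_stee(s.stee.value),
    }


def render_report(
    summaries: list[ValiditySummary],
    fmt: str = "markdown",
    include_average: bool = True,
) -> str:
    """Render per-condition validity blocks plus a per-device average row.

    ``fmt`` is ``"markdown"`` or ``"csv"``; machine-readable JSON output
    lives in :func:`wearvalid.sessions.write_summary_table`.
    """
    if not summaries:
        raise ValidationError("render_report needs at least one summary")
    if fmt not in ("markdown", "csv"):
        raise ValidationError(f"unknown report format {fmt!r}")

    rows: list[dict] = []
    for device in dict.fromkeys(s.device_id for s in summaries):
        per_dev = [s for s in summaries if s.device_id == device]
        rows.extend(summary_row(s) for s in per_dev)
        if include_average and not any(s.condition_id == "average" for s in per_dev):
            rows.append(summary_row(aggregate_conditions(per_dev)))

    cols = list(rows[0].keys())
    if fmt == "csv":
        lines = [",".join(cols)]
        for r in rows:
            lines.append(",".join(f'"{r[c]}"' if "," in str(r[c]) else str(r[c]) for c in cols))
        return "\n".join(lines) + "\n"
    header = "| " + " | ".join(cols) + " |"
    sep = "|" + "|".join(" --- " for _ in cols) + "|"
    body = ["| " + " | ".join(str(r[c]) for c in cols) + " |" for r in rows]
    return "\n".join([header, sep, *body]) + "\n"


def plot_stee(summaries: list[ValiditySummary], path: str) -> None:
    """Plot sTEE per condition with 90% confidence whiskers, one panel layout.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    devices = list(dict.fromkeys(s.device_id for s in summaries))
    conditions = list(dict.fromkeys(s.condition_id for s in summaries))
    width = 0.8 / max(len(devices), 1)
    for i, device in enumerate(devices):
        xs, ys, lo, hi = [], [], [], []
        for j, cond in enumerate(conditions):
            for s in summaries:
                if s.device_id == device and s.condition_id == cond:
                    xs.append(j + (i - (len(devices) - 1) / 2) * width)
                    ys.append(s.stee.value)
                    lo.append(max(s.stee.value - s.stee.lower, 0))
                    hi.append(
                        (s.stee.upper - s.stee.value)
                        if math.isfinite(s.stee.upper)
                        else 0
                    )
        ax.errorbar(xs, ys, yerr=[lo, hi], fmt="o", capsize=3, label=device)
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels(conditions, rotation=30, ha="right")
    ax.set_ylabel("sTEE (90% CL)")
    ax.axhline(0.1, ls=":", lw=0.8, color="grey")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
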