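"""Data structures for paired device-vs-criterion measurements.

The study design is a crossed layout: each participant performs every
activity condition while wearing every device alongside a criterion
instrument (chest-belt heart-rate strap, indirect calorimetry).  One
:class:`MeasurementRecord` holds one aggregated bout value pair; a
:class:`Cohort` bundles the records with the condition protocol and the
cohort constants needed downstream (mean body mass for MET derivation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "MeasurementRecord",
    "ConditionProtocol",
    "Cohort",
    "Estimate",
    "RegressionFit",
    "ValiditySummary",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One paired observation: criterion and device value for a single bout.

    Both values must be strictly positive (the analysis log-transforms them)
    and share the same unit within a dataset — beats per minute for heart
    rate, kcal per bout for energy expenditure.
    """

    participant_id: str
    device_id: str
    condition_id: str
    criterion_value: float
    device_value: float
    timestamp: float | None = None  # seconds from bout start, for raw samples

    def __post_init__(self) -> None:
        for name in ("criterion_value", "device_value"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{name} must be finite and > 0 (log transform), got {v!r}"
                )


@dataclass(frozen=True)
class ConditionProtocol:
    """An activity condition: label, bout duration, and criterion summary.

    ``criterion_mean``/``criterion_sd`` are the between-participant mean and
    SD of the criterion measurement for this condition (used by the
    synthetic generator and for absolute-error derivations).
    """

    condition_id: str
    label: str
    criterion_mean: float
    criterion_sd: float
    duration_min: float = 5.0
    speed_m_per_s: float | None = None

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValidationError(f"duration_min must be > 0, got {self.duration_min}")
        if self.criterion_mean <= 0:
            raise ValidationError(
                f"criterion_mean must be > 0, got {self.criterion_mean}"
            )
        if self.criterion_sd < 0:
            raise ValidationError(f"criterion_sd must be >= 0, got {self.criterion_sd}")


@dataclass
class Cohort:
    """A set of paired measurements plus the protocol they were taken under.

    Invariants enforced on construction:

    * every record's ``condition_id`` appears in the protocol;
    * per (device, condition) there is at most one aggregated record per
      participant (time series must be aggregated before building a Cohort).
    """

    records: list[MeasurementRecord]
    protocol: list[ConditionProtocol]
    body_mass_mean_kg: float = 70.1
    n_participants: int = field(default=0)  # 0 → derived from records

    def __post_init__(self) -> None:
        if self.body_mass_mean_kg <= 0:
            raise ValidationError(
                f"body_mass_mean_kg must be > 0, got {self.body_mass_mean_kg}"
            )
        known = {p.condition_id for p in self.protocol}
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.condition_id not in known:
                raise ValidationError(
                    f"record condition {rec.condition_id!r} not in protocol"
                )
            key = (rec.participant_id, rec.device_id, rec.condition_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate record for participant/device/condition {key}; "
                    "aggregate time series to one value per bout first"
                )
            seen.add(key)
        if self.n_participants == 0:
            self.n_participants = len({r.participant_id for r in self.records})

    # -- convenience accessors -------------------------------------------------

    def devices(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.device_id not in out:
                out.append(r.device_id)
        return out

    def conditions(self) -> list[str]:
        return [p.condition_id for p in self.protocol]

    def condition(self, condition_id: str) -> ConditionProtocol:
        for p in self.protocol:
            if p.condition_id == condition_id:
                return p
        raise KeyError(condition_id)

    def pairs(self, device_id: str, condition_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (criterion, device) value arrays for one analysis cell,
        ordered by participant id."""
        sel = sorted(
            (
                r
                for r in self.records
                if r.device_id == device_id and r.condition_id == condition_id
            ),
            key=lambda r: r.participant_id,
        )
        crit = np.array([r.criterion_value for r in sel], dtype=float)
        dev = np.array([r.device_value for r in sel], dtype=float)
        return crit, dev

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.records],
                "device_id": [r.device_id for r in self.records],
                "condition_id": [r.condition_id for r in self.records],
                "criterion": [r.criterion_value for r in self.records],
                "device": [r.device_value for r in self.records],
            }
        )


@dataclass(frozen=True)
class Estimate:
    """A point estimate with (optional) lower/upper 90% confidence limits."""

    value: float
    lower: float = math.nan
    upper: float = math.nan

    def __post_init__(self) -> None:
        if math.isfinite(self.lower) and math.isfinite(self.value):
            if self.lower > self.value + 1e-12:
                raise ValidationError(f"lower limit {self.lower} > value {self.value}")
        if math.isfinite(self.upper) and math.isfinite(self.value):
            if self.upper < self.value - 1e-12:
                raise ValidationError(f"upper limit {self.upper} < value {self.value}")

    def round(self, ndigits: int) -> "Estimate":
        def _r(x: float) -> float:
            return round(x, ndigits) if math.isfinite(x) else x

        return replace(self, value=_r(self.value), lower=_r(self.lower), upper=_r(self.upper))


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares fit of criterion on device, both on the 100·ln scale.

    ``tee_log`` is the typical error of the estimate: the residual standard
    deviation with n−2 degrees of freedom, in units of the 100·ln scale
    (≈ percent for small errors).  ``r_log`` is the Pearson correlation of
    the two log vectors.
    """

    slope: float
    intercept: float
    tee_log: float
    r_log: float
    n: int


@dataclass(frozen=True)
class ValiditySummary:
    """The per-device-per-condition validity block.

    Mirrors one table cell-group of a validity report: criterion mean (SD),
    standardized mean bias, Pearson r, CV%, and sTEE, each with 90%
    confidence limits.  ``flags`` records degeneracies (e.g. an undefined
    sTEE when r = 0) instead of raising at the summary level.
    """

    device_id: str
    condition_id: str
    n: int
    criterion_mean: float
    criterion_sd: float
    std_mean_bias: Estimate
    pearson_r: Estimate
    cv_pct: Estimate
    stee: Estimate
    flags: tuple[str, ...] = ()
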