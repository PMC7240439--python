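"""Reading, writing, and bout aggregation for paired-measurement tables.

Input is a long-format CSV (RFC-4180, UTF-8, header row) with one row per
participant × device × condition:

    participant_id,device_id,condition_id,criterion,device[,t_s]

When the optional ``t_s`` column is present the file holds time-stamped
samples (seconds from bout start) that must be aggregated to one value per
bout before analysis.  Summary tables round-trip losslessly through the
JSON dialect; CSV and markdown renderings are for human consumption.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    Cohort,
    ConditionProtocol,
    Estimate,
    MeasurementRecord,
    ValiditySummary,
)
from .exceptions import SchemaError, ValidationError
from .interpret import aggregate_conditions, render_report

__all__ = [
    "REQUIRED_COLUMNS",
    "read_measurements",
    "aggregate_bout",
    "aggregate_timeseries",
    "write_measurements",
    "write_summary_table",
    "read_summary_table",
]

REQUIRED_COLUMNS = ("participant_id", "device_id", "condition_id", "criterion", "device")
TIME_COLUMN = "t_s"


def _apply_dialect(df: pd.DataFrame, dialect: dict[str, str] | None) -> pd.DataFrame:
    """Rename file columns to the canonical names; ``dialect`` maps
    canonical name → column name in the file."""
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def _check_columns(df: pd.DataFrame, need) -> None:
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _check_positive(df: pd.DataFrame) -> None:
    for col in ("criterion", "device"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise ValidationError(
                f"non-positive or non-numeric {col!r} in data row {row}: "
                f"{df[col].iloc[row - 1]!r}"
            )


def read_measurements(
    path,
    dialect: dict[str, str] | None = None,
    protocol: list[ConditionProtocol] | None = None,
    body_mass_mean_kg: float = 70.1,
) -> Cohort:
    """Read an aggregated long-format CSV into a :class:`Cohort`.

    ``dialect`` maps canonical column names to the file's column names.
    If no ``protocol`` is given, one is derived from the data (per-condition
    criterion mean/SD, 5-minute default duration).  Row order is preserved;
    non-finite or non-positive measurement values are rejected with the
    offending row cited.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    df = _apply_dialect(pd.read_csv(p, float_precision="round_trip"), dialect)
    _check_columns(df, REQUIRED_COLUMNS)
    _check_positive(df)
    records = [
        MeasurementRecord(
            participant_id=str(r.participant_id),
            device_id=str(r.device_id),
            condition_id=str(r.condition_id),
            criterion_value=float(r.criterion),
            device_value=float(r.device),
        )
        for r in df.itertuples(index=False)
    ]
    if protocol is None:
        protocol = []
        for cid, grp in df.groupby("condition_id", sort=False):
            vals = grp["criterion"].astype(float)
            protocol.append(
                ConditionProtocol(
                    condition_id=str(cid),
                    label=str(cid),
                    criterion_mean=float(vals.mean()),
                    criterion_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                )
            )
    return Cohort(records=records, protocol=protocol, body_mass_mean_kg=body_mass_mean_kg)


def aggregate_bout(
    samples: pd.DataFrame,
    discard_initial_s: float = 0.0,
    *,
    participant_id: str | None = None,
    device_id: str | None = None,
    condition_id: str | None = None,
) -> MeasurementRecord:
    """Collapse time-stamped samples of one bout to a single record.

    ``samples`` needs columns ``t_s``, ``criterion`` and ``device`` (id
    columns are used when present, else the keyword ids).  Samples with
    ``t_s < discard_initial_s`` are dropped (transient at bout start);
    the retained samples are averaged arithmetically, so the result is
    invariant to sample order within the retained window.
    """
    if discard_initial_s < 0:
        raise ValidationError(f"discard_initial_s must be >= 0, got {discard_initial_s}")
    _check_columns(samples, (TIME_COLUMN, "criterion", "device"))
    kept = samples[samples[TIME_COLUMN].astype(float) >= discard_initial_s]
    if kept.empty:
        raise ValidationError("all samples discarded; empty bout")

    def _id(col: str, given: str | None) -> str:
        if col in samples.columns:
            vals = samples[col].unique()
            if len(vals) != 1:
                raise ValidationError(f"samples mix multiple {col} values: {vals!r}")
            return str(vals[0])
        if given is None:
            raise ValidationError(f"no {col} column and no {col} argument")
        return given

    return MeasurementRecord(
        participant_id=_id("participant_id", participant_id),
        device_id=_id("device_id", device_id),
        condition_id=_id("condition_id", condition_id),
        criterion_value=float(kept["criterion"].astype(float).mean()),
        device_value=float(kept["device"].astype(float).mean()),
    )


def aggregate_timeseries(
    df: pd.DataFrame, discard_initial_s: float = 0.0
) -> pd.DataFrame:
    """Aggregate a long time-series table to one row per bout.

    Groups by (participant_id, device_id, condition_id) and applies
    :func:`aggregate_bout`; returns an aggregated long-format frame.
    """
    _check_columns(df, REQUIRED_COLUMNS + (TIME_COLUMN,))
    rows = []
    for _, grp in df.groupby(
        ["participant_id", "device_id", "condition_id"], sort=False
    ):
        rec = aggregate_bout(grp, discard_initial_s)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "device_id": rec.device_id,
                "condition_id": rec.condition_id,
                "criterion": rec.criterion_value,
                "device": rec.device_value,
            }
        )
    return pd.DataFrame(rows)


def write_measurements(cohort: Cohort, path) -> None:
    """Write a cohort back to the canonical long-format CSV."""
    cohort.to_dataframe().to_csv(path, index=False)


def _summary_to_dict(s: ValiditySummary) -> dict:
    d = asdict(s)
    d["flags"] = list(s.flags)
    return d


def _summary_from_dict(d: dict) -> ValiditySummary:
    return ValiditySummary(
        device_id=d["device_id"],
        condition_id=d["condition_id"],
        n=int(d["n"]),
        criterion_mean=d["criterion_mean"],
        criterion_sd=d["criterion_sd"],
        std_mean_bias=Estimate(**d["std_mean_bias"]),
        pearson_r=Estimate(**d["pearson_r"]),
        cv_pct=Estimate(**d["cv_pct"]),
        stee=Estimate(**d["stee"]),
        flags=tuple(d.get("flags", ())),
    )


def _json_safe(obj):
    """Encode NaN/inf as strings so the JSON round trip is lossless and
    standard-compliant."""
    if isinstance(obj, float):
        if math.isnan(obj):
            return "NaN"
        if math.isinf(obj):
            return "Infinity" if obj > 0 else "-Infinity"
        return obj
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_json_safe(v) for v in obj]
    return obj


def _json_restore(obj):
    if obj == "NaN":
        return math.nan
    if obj == "Infinity":
        return math.inf
    if obj == "-Infinity":
        return -math.inf
    if isinstance(obj, dict):
        return {k: _json_restore(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_json_restore(v) for v in obj]
    return obj


def write_summary_table(
    summaries: list[ValiditySummary],
    path,
    fmt: str = "csv",
    include_average: bool = True,
) -> None:
    """Write validity summaries to ``path`` as csv, json, or markdown.

    One row per (device, condition) plus one "average" row per device.
    JSON stores full precision and round-trips via
    :func:`read_summary_table`; csv/markdown use the report rounding.
    """
    if not summaries:
        raise ValidationError("write_summary_table needs at least one summary")
    if fmt == "json":
        full = list(summaries)
        if include_average:
            for device in dict.fromkeys(s.device_id for s in summaries):
                per_dev = [s for s in summaries if s.device_id == device]
                if not any(s.condition_id == "average" for s in per_dev):
                    full.append(aggregate_conditions(per_dev))
        payload = _json_safe([_summary_to_dict(s) for s in full])
        Path(path).write_text(json.dumps(payload, indent=1, allow_nan=False) + "\n")
    elif fmt in ("csv", "markdown", "md"):
        text = render_report(
            summaries,
            fmt="markdown" if fmt in ("markdown", "md") else "csv",
            include_average=include_average,
        )
        Path(path).write_text(text)
    else:
        raise ValidationError(f"unknown summary format {fmt!r}")


def read_summary_table(path) -> list[ValiditySummary]:
    """Read summaries back from the JSON dialect (lossless round trip)."""
    payload = _json_restore(json.loads(Path(path).read_text()))
    return [_summary_from_dict(d) for d in payload]
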