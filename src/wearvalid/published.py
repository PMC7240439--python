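"""Published summary statistics of the four-wearable validation study.

The validation study this package reproduces reported, for 25 participants
performing seven 5-minute activity conditions (sitting; walking/running at
1.1, 1.9, 2.7, 3.6 and 4.1 m/s; intermittent multidirectional sprints)
while wearing four wrist devices, a per-device-per-condition block of
standardized mean bias, Pearson r, CV% and sTEE against criterion measures
(chest-belt strap for heart rate, indirect calorimetry for energy
expenditure).  The raw participant data were not deposited; the printed
point values below are therefore the inputs for every quantity that is
derivable from the report alone — MET levels, absolute errors, hourly
energy-expenditure errors, and the cross-condition average rows.

Values are transcribed exactly as printed (point estimates only).
"""

from __future__ import annotations

from .datamodel import ConditionProtocol, Estimate, ValiditySummary

__all__ = [
    "DEVICES",
    "DEVICE_LABELS",
    "CONDITION_IDS",
    "CONDITION_LABELS",
    "LOW_INTENSITY",
    "HIGH_INTENSITY",
    "BODY_MASS_KG",
    "N_PARTICIPANTS",
    "BOUT_MINUTES",
    "HR_CRITERION",
    "EE_CRITERION",
    "HR_STATS",
    "EE_STATS",
    "HR_AVERAGE",
    "EE_AVERAGE",
    "EE_GRAND_MEAN",
    "MET_PRINTED",
    "protocol",
    "published_summaries",
]

DEVICES = ("apple", "polar", "garmin", "fitbit")
DEVICE_LABELS = {
    "apple": "Apple Watch Series 4",
    "polar": "Polar Vantage V",
    "garmin": "Garmin Fenix 5",
    "fitbit": "Fitbit Versa",
}

CONDITION_IDS = ("sitting", "1.1ms", "1.9ms", "2.7ms", "3.6ms", "4.1ms", "sprint")
CONDITION_LABELS = {
    "sitting": "sitting",
    "1.1ms": "1.1 m/s",
    "1.9ms": "1.9 m/s",
    "2.7ms": "2.7 m/s",
    "3.6ms": "3.6 m/s",
    "4.1ms": "4.1 m/s",
    "sprint": "intermittent sprints",
}
_SPEEDS = {
    "sitting": 0.0,
    "1.1ms": 1.1,
    "1.9ms": 1.9,
    "2.7ms": 2.7,
    "3.6ms": 3.6,
    "4.1ms": 4.1,
    "sprint": None,  # shuttle sprints, no constant speed
}

# Discussion split: sitting and locomotion up to 2.7 m/s vs 3.6 m/s and faster.
LOW_INTENSITY = ("sitting", "1.1ms", "1.9ms", "2.7ms")
HIGH_INTENSITY = ("3.6ms", "4.1ms", "sprint")

BODY_MASS_KG = 70.1  # cohort mean body mass
N_PARTICIPANTS = 25
BOUT_MINUTES = 5.0

# Criterion mean (SD) per condition: heart rate in bpm, EE in kcal per 5-min bout.
HR_CRITERION = {
    "sitting": (68.8, 11.7),
    "1.1ms": (95.8, 25.0),
    "1.9ms": (127.0, 19.4),
    "2.7ms": (167.0, 16.5),
    "3.6ms": (170.0, 15.3),
    "4.1ms": (177.0, 8.5),
    "sprint": (153.0, 14.7),
}
EE_CRITERION = {
    "sitting": (7.6, 1.6),
    "1.1ms": (20.6, 4.1),
    "1.9ms": (38.3, 6.5),
    "2.7ms": (57.8, 11.0),
    "3.6ms": (60.5, 26.7),
    "4.1ms": (77.8, 46.6),
    "sprint": (80.4, 15.6),
}

# MET level printed next to each condition label (criterion EE × 12 / 70.1 kg).
MET_PRINTED = {
    "sitting": 1.3,
    "1.1ms": 3.5,
    "1.9ms": 6.6,
    "2.7ms": 9.9,
    "3.6ms": 10.4,
    "4.1ms": 13.3,
    "sprint": 13.8,
}

# Per-device point estimates, condition → (bias, r, cv_pct, stee).
HR_STATS = {
    "apple": {
        "sitting": (0.03, 0.99, 2.0, 0.12),
        "1.1ms": (0.01, 0.97, 2.9, 0.23),
        "1.9ms": (-0.02, 0.97, 2.9, 0.23),
        "2.7ms": (-0.13, 1.0, 0.9, 0.09),
        "3.6ms": (0.02, 0.94, 3.0, 0.35),
        "4.1ms": (-0.27, 0.85, 4.3, 0.62),
        "sprint": (0.12, 0.92, 3.5, 0.38),
    },
    "polar": {
        "sitting": (-0.06, 0.99, 2.2, 0.13),
        "1.1ms": (-0.07, 0.89, 5.5, 0.54),
        "1.9ms": (-0.34, 0.91, 5.4, 0.46),
        "2.7ms": (-0.37, 0.88, 5.9, 0.53),
        "3.6ms": (-0.75, 0.86, 4.9, 0.59),
        "4.1ms": (-0.72, 0.89, 3.9, 0.50),
        "sprint": (-0.99, 0.75, 6.7, 0.88),
    },
    "garmin": {
        "sitting": (0.12, 0.89, 7.7, 0.63),
        "1.1ms": (0.12, 0.85, 5.8, 0.62),
        "1.9ms": (0.06, 0.83, 9.2, 0.68),
        "2.7ms": (-0.56, 0.63, 8.3, 1.24),
        "3.6ms": (-0.40, 0.82, 8.9, 0.69),
        "4.1ms": (-1.47, 0.82, 2.88, 0.69),
        "sprint": (-1.75, 0.58, 8.4, 1.44),
    },
    "fitbit": {
        "sitting": (-0.06, 0.91, 8.0, 0.47),
        "1.1ms": (-0.28, 0.57, 9.6, 1.43),
        "1.9ms": (-0.05, 0.54, 19.1, 1.58),
        "2.7ms": (-0.82, 0.52, 8.5, 1.64),
        "3.6ms": (-1.17, 0.82, 4.1, 0.70),
        "4.1ms": (-2.06, 0.68, 3.22, 1.09),
        "sprint": (-2.01, 0.53, 9.0, 1.94),
    },
}

EE_STATS = {
    "apple": {
        "sitting": (2.59, 0.46, 26.6, 1.84),
        "1.1ms": (2.63, 0.71, 15.1, 0.99),
        "1.9ms": (1.58, 0.71, 13.5, 0.99),
        "2.7ms": (0.79, 0.80, 19.0, 0.76),
        "3.6ms": (0.32, 0.95, 20.3, 0.34),
        "4.1ms": (0.34, 0.93, 27.1, 0.39),
        "sprint": (1.83, 0.66, 25.4, 1.15),
    },
    "polar": {
        "sitting": (0.25, 0.41, 28.0, 1.33),
        "1.1ms": (1.29, 0.67, 16.3, 1.10),
        "1.9ms": (0.27, 0.49, 17.1, 0.65),
        "2.7ms": (-0.09, 0.72, 21.9, 0.97),
        "3.6ms": (-0.05, 0.95, 20.7, 0.34),
        "4.1ms": (-0.11, 0.95, 22.7, 0.32),
        "sprint": (0.23, 0.85, 17.5, 0.63),
    },
    "garmin": {
        "sitting": (1.74, 0.23, 20.9, 4.24),
        "1.1ms": (-0.05, 0.20, 16.8, 4.86),
        "1.9ms": (-1.15, 0.21, 15.9, 4.62),
        "2.7ms": (-0.04, 0.57, 17.1, 1.43),
        "3.6ms": (0.19, 0.84, 34.5, 0.64),
        "4.1ms": (0.25, 0.91, 33.1, 0.46),
        "sprint": (-0.82, 0.21, 17.9, 4.62),
    },
    "fitbit": {
        "sitting": (-0.72, 0.52, 17.1, 1.65),
        "1.1ms": (4.16, 0.88, 8.0, 0.53),
        "1.9ms": (0.88, 0.78, 11.2, 0.81),
        "2.7ms": (-0.06, 0.74, 14.1, 0.90),
        "3.6ms": (-0.06, 0.76, 32.3, 0.87),
        "4.1ms": (0.13, 0.92, 29.9, 0.41),
        "sprint": (-1.25, 0.42, 20.8, 1.64),
    },
}

# Printed "average of the values at all different intensities" rows,
# device → (bias, r, cv_pct, stee); kept for cross-checks of the
# aggregation convention.
HR_AVERAGE = {
    "apple": (0.03, 0.95, 2.79, 0.29),
    "polar": (-0.47, 0.88, 4.93, 0.52),
    "garmin": (-0.55, 0.77, 7.30, 0.86),
    "fitbit": (-0.92, 0.65, 8.79, 1.26),
}
EE_AVERAGE = {
    "apple": (1.44, 0.75, 21.0, 0.92),
    "polar": (0.26, 0.72, 20.6, 0.76),
    "garmin": (0.02, 0.45, 22.3, 2.98),
    "fitbit": (0.44, 0.72, 19.1, 0.97),
}
HR_GRAND_MEAN = 137.0  # bpm, printed average-row criterion mean
EE_GRAND_MEAN = 49.0  # kcal per 5-min bout, printed average-row criterion mean


def protocol(measure: str = "hr") -> list[ConditionProtocol]:
    """The seven-condition study protocol with printed criterion mean/SD.

    ``measure`` selects which criterion summary is attached: ``"hr"``
    (heart rate, bpm) or ``"ee"`` (energy expenditure, kcal per bout).
    """
    crit = {"hr": HR_CRITERION, "ee": EE_CRITERION}[measure]
    return [
        ConditionProtocol(
            condition_id=cid,
            label=CONDITION_LABELS[cid],
            criterion_mean=crit[cid][0],
            criterion_sd=crit[cid][1],
            duration_min=BOUT_MINUTES,
            speed_m_per_s=_SPEEDS[cid],
        )
        for cid in CONDITION_IDS
    ]


def published_summaries(measure: str = "hr") -> list[ValiditySummary]:
    """The printed per-device-per-condition blocks as ValiditySummary objects.

    Point values only; confidence limits are NaN (the derivable quantities —
    absolute errors, averages, MET levels — use points alone).
    """
    stats = {"hr": HR_STATS, "ee": EE_STATS}[measure]
    crit = {"hr": HR_CRITERION, "ee": EE_CRITERION}[measure]
    out: list[ValiditySummary] = []
    for device in DEVICES:
        for cid in CONDITION_IDS:
            bias, r, cv, stee = stats[device][cid]
            mean, sd = crit[cid]
            out.append(
                ValiditySummary(
                    device_id=device,
                    condition_id=cid,
                    n=N_PARTICIPANTS,
                    criterion_mean=mean,
                    criterion_sd=sd,
                    std_mean_bias=Estimate(bias),
                    pearson_r=Estimate(r),
                    cv_pct=Estimate(cv),
                    stee=Estimate(stee),
                )
            )
    return out
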