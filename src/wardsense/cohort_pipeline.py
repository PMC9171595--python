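"""Cohort filtering, clinical-sensor merging, and descriptive summaries.

The analysis cohort keeps patients with at least three valid sensor days
(a valid day has at least four hours of watch wear, inclusive) and at least
three PT/OT sessions (pooled across disciplines). Each clinical assessment
day is merged with its own or the closest valid sensor day; matches with an
absolute gap above three days are dropped and accounted for. Weekly
descriptives (median and IQR per measure) use admission-day / week-k bins,
while the longitudinal models use continuous weeks — two deliberately
separate time conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import InclusionCriteria
from .errors import UndefinedGroupError


@dataclass(frozen=True)
class MergedObservation:
    """One clinical assessment paired with its matched sensor day."""

    patient_id: str
    assessment_day: int
    sensor_day: int
    gap_days: int
    time_weeks: float
    discipline: str
    measure: str
    value: float
    sensor: Mapping[str, float] = field(default_factory=dict)


def valid_day(wear_time_s: float, criteria: InclusionCriteria) -> bool:
    """A valid sensor day has >= min wear hours (inclusive boundary)."""
    return wear_time_s >= criteria.min_wear_hours_per_day * 3600.0


def count_sessions(assessments: pd.DataFrame) -> pd.Series:
    """Sessions per patient: distinct (day, discipline) batteries, PT+OT pooled."""
    return (
        assessments.drop_duplicates(["patient_id", "day_index", "discipline"])
        .groupby("patient_id", observed=True)
        .size()
    )


def apply_inclusion_criteria(
    daily_features: pd.DataFrame,
    assessments: pd.DataFrame,
    criteria: InclusionCriteria = InclusionCriteria(),
) -> tuple[list[str], dict]:
    """Select the analysis cohort and return (included ids, consort accounting).

    A patient is included iff their number of valid sensor days >= 3 AND their
    number of PT/OT sessions (pooled) >= 3. The consort dict counts, per rule,
    how many patients fail it (a patient can fail both).
    """
    df = daily_features.copy()
    df["valid"] = df["wear_time_s"].astype(float) >= (
        criteria.min_wear_hours_per_day * 3600.0
    )
    all_ids = sorted(
        set(df["patient_id"].astype(str)) | set(assessments["patient_id"].astype(str))
    )
    valid_days = (
        df.loc[df["valid"]].groupby("patient_id", observed=True).size()
    )
    sessions = count_sessions(assessments)

    included, fail_days, fail_sessions = [], [], []
    for pid in all_ids:
        ok_days = valid_days.get(pid, 0) >= criteria.min_valid_days
        ok_sessions = sessions.get(pid, 0) >= criteria.min_sessions
        if not ok_days:
            fail_days.append(pid)
        if not ok_sessions:
            fail_sessions.append(pid)
        if ok_days and ok_sessions:
            included.append(pid)
    consort = {
        "n_input": len(all_ids),
        "n_included": len(included),
        "n_excluded": len(all_ids) - len(included),
        "n_failed_min_valid_days": len(fail_days),
        "n_failed_min_sessions": len(fail_sessions),
        "failed_min_valid_days": fail_days,
        "failed_min_sessions": fail_sessions,
    }
    return included, consort


#: Sensor covariates carried onto each merged observation.
SENSOR_COVARIATES = (
    "overall_EI",
    "resident_room_EI",
    "therapy_room_EI",
    "sitting_EI",
    "standing_EI",
    "laying_EI",
)


def merge_clinical_sensor(
    assessments: pd.DataFrame,
    daily_features: pd.DataFrame,
    criteria: InclusionCriteria = InclusionCriteria(),
    included: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Pair each assessment with its nearest valid sensor day.

    Only valid sensor days are eligible. The match minimizes |gap|, ties going
    to the earlier sensor day; assessments whose nearest valid day is more
    than ``max_merge_gap_days`` away are dropped and counted. Returns the
    merged long table and a drop log; emitted + dropped = input rows.
    """
    feats = daily_features.copy()
    feats = feats.loc[
        feats["wear_time_s"].astype(float)
        >= criteria.min_wear_hours_per_day * 3600.0
    ]
    assess = assessments.copy()
    if included is not None:
        keep = set(map(str, included))
        feats = feats.loc[feats["patient_id"].astype(str).isin(keep)]
        assess = assess.loc[assess["patient_id"].astype(str).isin(keep)]

    days_by_patient: dict[str, np.ndarray] = {
        str(pid): np.sort(g["day_index"].to_numpy(dtype=int))
        for pid, g in feats.groupby("patient_id", observed=True)
    }
    feat_lookup = feats.set_index(["patient_id", "day_index"])

    rows, dropped = [], []
    for r in assess.itertuples(index=False):
        pid = str(r.patient_id)
        days = days_by_patient.get(pid)
        if days is None or len(days) == 0:
            dropped.append((pid, int(r.day_index), r.measure, "no_valid_sensor_days"))
            continue
        gaps = np.abs(days - int(r.day_index))
        best_gap = gaps.min()
        if best_gap > criteria.max_merge_gap_days:
            dropped.append((pid, int(r.day_index), r.measure, "gap_exceeds_max"))
            continue
        sensor_day = int(days[gaps == best_gap].min())  # tie -> earlier day
        srow = feat_lookup.loc[(r.patient_id, sensor_day)]
        rec = {
            "patient_id": pid,
            "assessment_day": int(r.day_index),
            "sensor_day": sensor_day,
            "gap_days": int(best_gap),
            "time_weeks": int(r.day_index) / 7.0,
            "discipline": r.discipline,
            "measure": r.measure,
            "value": float(r.value),
        }
        for cov in SENSOR_COVARIATES:
            rec[cov] = float(srow[cov]) if cov in srow.index else np.nan
        rows.append(rec)
    merged = pd.DataFrame(rows)
    log = {
        "n_input": len(assess),
        "n_merged": len(rows),
        "n_dropped": len(dropped),
        "dropped": [
            {"patient_id": p, "day_index": d, "measure": m, "reason": why}
            for p, d, m, why in dropped
        ],
    }
    return merged, log


def week_bin(day_index: int) -> Optional[str]:
    """Descriptive-statistics bin: admission = day 0; week k = days 7(k-1)+1..7k."""
    if day_index == 0:
        return "admission"
    if day_index < 0:
        return None
    k = int(np.ceil(day_index / 7.0))
    return f"week_{k}"


def weekly_descriptives(
    values: pd.DataFrame,
    value_col: str = "value",
    day_col: str = "assessment_day",
    measure_col: str = "measure",
    max_week: int = 3,
) -> pd.DataFrame:
    """Per-measure, per-bin N / median / Q1 / Q3 table.

    Quartiles use linear interpolation between order statistics (the numpy
    default). Empty bins appear with N=0 and absent statistics.
    """
    df = values.copy()
    df["bin"] = df[day_col].astype(int).map(week_bin)
    bins = ["admission"] + [f"week_{k}" for k in range(1, max_week + 1)]
    rows = []
    for measure in sorted(df[measure_col].unique()):
        sub = df.loc[df[measure_col] == measure]
        for b in bins:
            v = sub.loc[sub["bin"] == b, value_col].to_numpy(dtype=float)
            if v.size:
                rows.append(
                    (measure, b, v.size, float(np.median(v)),
                     float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)))
                )
            else:
                rows.append((measure, b, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["measure", "bin", "n", "median", "q1", "q3"]
    )


def demographic_summary(
    patients: pd.DataFrame,
    strata: Sequence[str] = ("sex", "race"),
) -> pd.DataFrame:
    """Table of counts and within-group percentages by outcome group.

    Reports per group: patient count and share of the cohort, age mean (SD),
    and counts with within-group percentages for each categorical stratum.
    Percentages for an empty group are reported absent, not 0/0.
    """
    total = len(patients)
    groups = ["community", "hospital"]
    rows = []
    for g in groups:
        sub = patients.loc[patients["outcome_group"] == g]
        n = len(sub)
        pct = 100.0 * n / total if total else np.nan
        rows.append(("subjects", "n (%)", g, n, round(pct, 1) if total else np.nan))
        if n:
            rows.append(
                ("age", "mean (SD)", g, round(float(sub["age"].mean()), 1),
                 round(float(sub["age"].std(ddof=1)), 1) if n > 1 else np.nan)
            )
        else:
            rows.append(("age", "mean (SD)", g, np.nan, np.nan))
        for stratum in strata:
            for level in sorted(patients[stratum].astype(str).unique()):
                cnt = int((sub[stratum].astype(str) == level).sum())
                lpct = round(100.0 * cnt / n, 1) if n else np.nan
                rows.append((stratum, level, g, cnt, lpct))
    return pd.DataFrame(
        rows, columns=["parameter", "level", "group", "value", "pct_or_sd"]
    )


def group_sizes(patients: pd.DataFrame) -> pd.Series:
    sizes = patients.groupby("outcome_group", observed=True).size()
    if sizes.empty:
        raise UndefinedGroupError("no patients")
    return sizes
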