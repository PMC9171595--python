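"""Per-patient-day feature fusion: energy intensities, times, occurrences.

The window MAD is treated as an energy rate, so a window's energy is
MAD x duration and the *energy intensity* (EI) of any category (an activity,
a room, or the whole day) is the total energy over the category divided by
the time spent in it — i.e. a time-weighted mean MAD — multiplied by a
reporting scale kappa (default 1000) that puts typical values in the teens.
Categories with zero time get a missing (absent) EI, never zero, so that
longitudinal models are not biased by structurally absent days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import ACTIVITIES, SEDENTARY_ACTIVITIES
from .errors import UndefinedWindowError

#: Reporting scale for energy intensities.
DEFAULT_KAPPA = 1000.0

#: EI columns of the daily feature vector, in output order.
EI_COLUMNS = (
    "overall_EI",
    "resident_room_EI",
    "therapy_room_EI",
    "sitting_EI",
    "standing_EI",
    "laying_EI",
    "walking_EI",
)


@dataclass
class DailyFeatureVector:
    """All sensor-derived features of one patient-day."""

    patient_id: str
    day_index: int
    wear_time_s: float
    overall_EI: Optional[float] = None
    resident_room_EI: Optional[float] = None
    therapy_room_EI: Optional[float] = None
    sitting_EI: Optional[float] = None
    standing_EI: Optional[float] = None
    laying_EI: Optional[float] = None
    walking_EI: Optional[float] = None
    time_by_activity: dict[str, float] = field(default_factory=dict)
    time_by_location: dict[str, float] = field(default_factory=dict)
    displacement_total_m: float = 0.0
    occurrences: dict[str, int] = field(default_factory=dict)
    sedentary_fraction: Optional[float] = None

    def as_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "day_index": self.day_index,
            "wear_time_s": self.wear_time_s,
        }
        for col in EI_COLUMNS:
            row[col] = getattr(self, col)
        for act in ACTIVITIES:
            row[f"time_{act}_s"] = self.time_by_activity.get(act, 0.0)
        for loc, t in sorted(self.time_by_location.items()):
            row[f"time_loc_{loc}_s"] = t
        row["displacement_total_m"] = self.displacement_total_m
        for loc, n in sorted(self.occurrences.items()):
            row[f"occ_{loc}"] = n
        row["sedentary_fraction"] = self.sedentary_fraction
        return row


def window_energy(mad: float, duration_s: float, worn: bool = True) -> float:
    """Energy of one worn window: MAD x duration (m/s^2 x s).

    Unworn windows carry no energy and must be excluded (not zeroed);
    requesting their energy is an error.
    """
    if not worn:
        raise UndefinedWindowError("unworn window has no defined energy")
    return mad * duration_s


def energy_intensity(
    mads: np.ndarray,
    durations: np.ndarray,
    kappa: float = DEFAULT_KAPPA,
) -> Optional[float]:
    """kappa-scaled total energy over total time for one category of windows.

    Returns None (missing) when the category holds no time at all.
    """
    durations = np.asarray(durations, dtype=float)
    total_time = durations.sum()
    if total_time <= 0:
        return None
    mads = np.asarray(mads, dtype=float)
    return float(kappa * (mads * durations).sum() / total_time)


def summarize_day(
    labeled_windows: pd.DataFrame,
    patient_id: str,
    day_index: int,
    occurrences: Optional[Mapping[str, int]] = None,
    kappa: float = DEFAULT_KAPPA,
    displacement_theta: float = 0.02,
) -> DailyFeatureVector:
    """Fuse one day's labeled worn windows into a DailyFeatureVector.

    ``labeled_windows`` needs columns (mad, duration_s, worn, activity,
    location); unworn rows are dropped here. A day with no worn windows is
    emitted with zero wear time and all features absent.
    """
    w = labeled_windows.loc[labeled_windows["worn"].astype(bool)]
    vec = DailyFeatureVector(
        patient_id=patient_id, day_index=day_index, wear_time_s=0.0,
        occurrences=dict(occurrences or {}),
    )
    if len(w) == 0:
        return vec

    mads = w["mad"].to_numpy(dtype=float)
    durs = w["duration_s"].to_numpy(dtype=float)
    acts = np.asarray(w["activity"].astype(str))
    locs = np.asarray(w["location"].astype(str))

    vec.wear_time_s = float(durs.sum())
    vec.overall_EI = energy_intensity(mads, durs, kappa)
    for act in ACTIVITIES:
        sel = acts == act
        vec.time_by_activity[act] = float(durs[sel].sum())
        setattr(
            vec,
            f"{act}_EI",
            energy_intensity(mads[sel], durs[sel], kappa),
        )
    for loc in np.unique(locs):
        sel = locs == loc
        vec.time_by_location[loc] = float(durs[sel].sum())
    vec.resident_room_EI = energy_intensity(
        mads[locs == "resident_room"], durs[locs == "resident_room"], kappa
    )
    vec.therapy_room_EI = energy_intensity(
        mads[locs == "therapy_area"], durs[locs == "therapy_area"], kappa
    )
    disp = np.where(mads >= displacement_theta, 0.5 * mads * durs**2, 0.0)
    vec.displacement_total_m = float(disp.sum())
    sed_time = sum(
        vec.time_by_activity.get(a, 0.0) for a in SEDENTARY_ACTIVITIES
    )
    vec.sedentary_fraction = sed_time / vec.wear_time_s
    return vec


def summarize_cohort_days(
    labeled_windows: pd.DataFrame,
    occurrences: Optional[pd.DataFrame] = None,
    kappa: float = DEFAULT_KAPPA,
) -> pd.DataFrame:
    """Vectorized per-patient-day feature table for a whole cohort.

    Equivalent to calling :func:`summarize_day` per patient-day (asserted in
    the test suite) but grouped with pandas for cohort-scale runs.
    ``occurrences`` (patient_id, day_index, location, n_occurrences) is
    optional and joined in as ``occ_<location>`` columns.
    """
    w = labeled_windows.loc[labeled_windows["worn"].astype(bool)].copy()
    if len(w) == 0:
        return pd.DataFrame(
            columns=["patient_id", "day_index", "wear_time_s", *EI_COLUMNS,
                     "sedentary_fraction"]
        )
    w["energy"] = w["mad"].to_numpy(dtype=float) * w["duration_s"].to_numpy(dtype=float)
    keys = ["patient_id", "day_index"]

    base = w.groupby(keys, observed=True).agg(
        wear_time_s=("duration_s", "sum"), total_energy=("energy", "sum")
    )
    base["overall_EI"] = kappa * base["total_energy"] / base["wear_time_s"]

    def _cat_ei(mask: pd.Series, name: str) -> None:
        sub = w.loc[np.asarray(mask)]
        g = sub.groupby(keys, observed=True).agg(
            t=("duration_s", "sum"), e=("energy", "sum")
        )
        base[name] = kappa * g["e"] / g["t"]

    _cat_ei(w["location"].astype(str) == "resident_room", "resident_room_EI")
    _cat_ei(w["location"].astype(str) == "therapy_area", "therapy_room_EI")
    acts = w["activity"].astype(str)
    for act in ACTIVITIES:
        _cat_ei(acts == act, f"{act}_EI")
        t = w.loc[np.asarray(acts == act)].groupby(keys, observed=True)["duration_s"].sum()
        base[f"time_{act}_s"] = t.reindex(base.index, fill_value=0.0)

    sed = sum(base[f"time_{a}_s"] for a in SEDENTARY_ACTIVITIES)
    base["sedentary_fraction"] = sed / base["wear_time_s"]
    disp = w.assign(
        d=np.where(
            w["mad"].to_numpy(dtype=float) >= 0.02,
            0.5 * w["mad"].to_numpy(dtype=float) * w["duration_s"].to_numpy(dtype=float) ** 2,
            0.0,
        )
    )
    base["displacement_total_m"] = disp.groupby(keys, observed=True)["d"].sum()
    base = base.drop(columns=["total_energy"]).reset_index()

    if occurrences is not None and len(occurrences):
        occ_wide = (
            occurrences.pivot_table(
                index=keys, columns="location", values="n_occurrences",
                aggfunc="sum", fill_value=0, observed=True,
            )
            .add_prefix("occ_")
            .reset_index()
        )
        base = base.merge(occ_wide, on=keys, how="left")
        occ_cols = [c for c in base.columns if c.startswith("occ_")]
        base[occ_cols] = base[occ_cols].fillna(0).astype(int)
    return base


def is_missing(value) -> bool:
    """True for an absent feature value (None or NaN)."""
    return value is None or (isinstance(value, float) and math.isnan(value))
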