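"""Activity classification, beacon localization, and dwell occurrences.

Each worn 10-s window gets exactly one activity label (laying, sitting,
standing, walking) from a seed-deterministic reference classifier over the
eight window features (MAD plus the seven time/frequency features), and one
location label from the beacon with the highest median RSSI inside the
window. Window-level locations are run-length encoded into maximal dwell
intervals; an *occurrence* of a location is one maximal stay strictly longer
than 40 s there.

The reference classifier stands in for the prior validated activity model of
the monitoring system; its contract is the accuracy floor (>= 0.90 balanced
accuracy on default synthetic regimes), not any particular model family. A
truth-bypass mode (using generator ground-truth labels directly) lets the
statistical pipeline be tested independently of classifier quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import ACTIVITIES, UNKNOWN_LOCATION
from .errors import IntegrityError, LabelingError, TrainingError
from .signal_features import FEATURE_ORDER

#: Dwell threshold (s): a stay must be strictly longer than this to count.
DEFAULT_OCCURRENCE_TAU_S = 40.0
#: Median RSSI below this floor maps a window to "unknown".
DEFAULT_RSSI_FLOOR_DBM = -90.0

_MIN_WINDOWS_PER_CLASS = 50


@dataclass
class ClassifierModel:
    """A trained, seed-deterministic activity classifier."""

    kind: str
    estimator: object
    feature_order: tuple[str, ...]
    training_seed: int
    classes: tuple[str, ...] = tuple(ACTIVITIES)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.feature_order)].to_numpy(dtype=float)
        proba = self.estimator.predict_proba(X)
        # Ties broken by fixed class order laying < sitting < standing < walking:
        # argmax returns the first maximal index, and columns are in that order.
        order = [list(self.estimator.classes_).index(c) for c in self.classes]
        return np.asarray(self.classes)[np.argmax(proba[:, order], axis=1)]


@dataclass(frozen=True)
class LocationInterval:
    """One maximal run of consecutive windows at the same location."""

    patient_id: Optional[str]
    day_index: Optional[int]
    start_s: float
    end_s: float
    location: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def train_reference_classifier(
    labeled_windows: pd.DataFrame, seed: int
) -> ClassifierModel:
    """Train the reference activity classifier on labeled feature windows.

    ``labeled_windows`` needs the eight FEATURE_ORDER columns plus an
    ``activity`` column covering all four classes with at least 50 windows
    each. Deterministic given data and seed.
    """
    counts = labeled_windows["activity"].value_counts()
    for cls in ACTIVITIES:
        if counts.get(cls, 0) < _MIN_WINDOWS_PER_CLASS:
            raise TrainingError(
                f"class {cls!r} has {counts.get(cls, 0)} windows; "
                f"need >= {_MIN_WINDOWS_PER_CLASS}"
            )
    X = labeled_windows[list(FEATURE_ORDER)].to_numpy(dtype=float)
    y = labeled_windows["activity"].to_numpy()
    est = RandomForestClassifier(
        n_estimators=60, max_depth=8, random_state=seed, n_jobs=1
    )
    est.fit(X, y)
    return ClassifierModel(
        kind="random_forest",
        estimator=est,
        feature_order=tuple(FEATURE_ORDER),
        training_seed=seed,
    )


def classify_activity(
    features: pd.DataFrame,
    model: ClassifierModel,
    worn: Optional[Sequence[bool]] = None,
) -> np.ndarray:
    """One activity label per worn window.

    Raises LabelingError if any window passed in is unworn — unworn windows
    carry no features and must be excluded upstream.
    """
    if worn is not None and not np.all(np.asarray(worn, dtype=bool)):
        raise LabelingError("cannot label unworn windows")
    if len(features) == 0:
        return np.array([], dtype=object)
    return model.predict(features)


def localize_window(
    pings: pd.DataFrame,
    facility_map: Mapping[str, str],
    rssi_floor_dbm: float = DEFAULT_RSSI_FLOOR_DBM,
) -> str:
    """Location of the beacon with the highest median RSSI in the window.

    Returns "unknown" when there are no pings or the best median RSSI falls
    below the floor. Ties go to the lexicographically smallest beacon id.
    Raises IntegrityError for a ping from a beacon absent from the map.
    """
    if len(pings) == 0:
        return UNKNOWN_LOCATION
    unknown_beacons = set(pings["beacon_id"]) - set(facility_map)
    if unknown_beacons:
        raise IntegrityError(
            f"beacon id(s) not in facility map: {sorted(unknown_beacons)}"
        )
    medians = pings.groupby("beacon_id", observed=True)["rssi_dbm"].median()
    medians = medians.sort_index()  # lexicographic tie-break
    best = medians.idxmax()  # first maximal index wins
    if medians.loc[best] < rssi_floor_dbm:
        return UNKNOWN_LOCATION
    return facility_map[best]


def segment_locations(
    locations: Sequence[str],
    window_duration_s: float = 10.0,
    start_s: float = 0.0,
    patient_id: Optional[str] = None,
    day_index: Optional[int] = None,
) -> list[LocationInterval]:
    """Run-length encode per-window locations into maximal dwell intervals."""
    locations = list(locations)
    if not locations:
        return []
    out: list[LocationInterval] = []
    run_start = 0
    for i in range(1, len(locations) + 1):
        if i == len(locations) or locations[i] != locations[run_start]:
            out.append(
                LocationInterval(
                    patient_id=patient_id,
                    day_index=day_index,
                    start_s=start_s + run_start * window_duration_s,
                    end_s=start_s + i * window_duration_s,
                    location=locations[run_start],
                )
            )
            run_start = i
    return out


def count_occurrences(
    intervals: Sequence[LocationInterval],
    location: str,
    tau_s: float = DEFAULT_OCCURRENCE_TAU_S,
) -> int:
    """Number of maximal stays at ``location`` strictly longer than tau_s."""
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    return sum(
        1 for iv in intervals if iv.location == location and iv.duration_s > tau_s
    )


def occurrences_by_location(
    intervals: Sequence[LocationInterval],
    locations: Sequence[str],
    tau_s: float = DEFAULT_OCCURRENCE_TAU_S,
) -> dict[str, int]:
    """Occurrence counts for every listed location."""
    return {loc: count_occurrences(intervals, loc, tau_s) for loc in locations}


def occurrence_matrix(
    occurrences: pd.DataFrame, group_assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Per-patient-normalized occurrence counts, location x group.

    ``occurrences`` has columns (patient_id, location, n_occurrences) — with
    one or more rows per patient-day-location, summed here. Every entry is the
    group's total occurrences at that location divided by the number of
    patients in the group (including patients with zero occurrences).
    Raises UndefinedGroupError for an empty group.
    """
    from .errors import UndefinedGroupError

    groups = pd.Series(dict(group_assignment), name="group")
    if len(groups) == 0:
        raise UndefinedGroupError("no patients in any group")
    sizes = groups.value_counts()
    if (sizes == 0).any():  # pragma: no cover - value_counts drops zeros
        raise UndefinedGroupError("empty group")

    occ = occurrences.copy()
    occ["group"] = occ["patient_id"].map(groups)
    if occ["group"].isna().any():
        missing = occ.loc[occ["group"].isna(), "patient_id"].unique()
        raise IntegrityError(f"patients without group assignment: {list(missing)}")
    totals = (
        occ.groupby(["location", "group"], observed=True)["n_occurrences"]
        .sum()
        .unstack("group", fill_value=0.0)
    )
    # Include groups with no occurrences at all, then normalize by group size.
    for g in sizes.index:
        if g not in totals.columns:
            totals[g] = 0.0
    totals = totals[sorted(totals.columns)]
    return totals.div(sizes, axis=1).astype(float)
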