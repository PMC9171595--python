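"""Configuration objects for simulation and cohort analysis.

``SimulationConfig`` encodes the monitoring protocol being emulated: a daily
09:00-18:00 smartwatch wear window, one scheduled hour in the facility's
therapy area, strongly sedentary behaviour (walking well under 1% of wear
time), weekly PT/OT assessment batteries, and day-level watch non-compliance.
``InclusionCriteria`` encodes the analysis filters: at least three valid
sensor days, at least four hours of wear per valid day, at least three
PT/OT sessions, and a maximum clinical-to-sensor merge gap of three days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError

#: Canonical activity classes, in fixed tie-break order.
ACTIVITIES: tuple[str, ...] = ("laying", "sitting", "standing", "walking")

#: Activities counted as sedentary time.
SEDENTARY_ACTIVITIES: frozenset[str] = frozenset({"laying", "sitting", "standing"})

#: Locations every facility map must provide.
REQUIRED_LOCATIONS: frozenset[str] = frozenset(
    {"resident_room", "therapy_area", "bathroom"}
)

#: Sentinel location when no beacon is audible.
UNKNOWN_LOCATION = "unknown"


def default_facility_map() -> dict[str, str]:
    """One beacon per location of interest; beacon ids sort deterministically."""
    return {
        "b_bath": "bathroom",
        "b_room": "resident_room",
        "b_therapy": "therapy_area",
    }


def _parse_clock(value: str, fieldname: str) -> int:
    """Parse 'HH:MM' to seconds since midnight."""
    try:
        hh, mm = value.split(":")
        sec = int(hh) * 3600 + int(mm) * 60
    except (ValueError, AttributeError) as exc:
        raise ConfigurationError(f"{fieldname}: expected 'HH:MM', got {value!r}") from exc
    if not 0 <= sec < 24 * 3600:
        raise ConfigurationError(f"{fieldname}: {value!r} outside 00:00-23:59")
    return sec


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic skilled-nursing-facility cohort.

    Defaults reproduce the monitored protocol: 110 patients with a ~95/5
    community/hospital discharge split, a 21-day rehabilitation course,
    09:00-18:00 wear, one hour of daily therapy, and a walking fraction of
    0.2% of wear time.
    """

    n_patients: int = 110
    p_hospital: float = 5 / 110
    n_days: int = 21
    wear_start: str = "09:00"
    wear_end: str = "18:00"
    sample_rate_hz: float = 25.0
    mode: str = "window"  # {"raw", "window"}
    window_duration_s: float = 10.0
    therapy_minutes_per_day: float = 60.0
    activity_mad_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "laying": 0.005,
            "sitting": 0.012,
            "standing": 0.022,
            "walking": 0.080,
        }
    )
    walking_fraction: float = 0.002
    p_missing_day: float = 0.10
    beacon_map_spec: Mapping[str, str] = field(default_factory=default_facility_map)
    assessment_days: Sequence[int] = (0, 7, 14, 21)
    latent_slope_community: float = 0.04
    latent_slope_hospital: float = -0.02
    score_noise_sd: float = 0.5
    seed: int = 0

    # Secondary knobs (documented in docs/methods.md).
    mad_window_sigma: float = 0.15  # lognormal window-to-window MAD jitter (log scale)
    mobility_mean: float = 1.05  # baseline latent-mobility mean (community)
    mobility_sd: float = 0.12
    hospital_mobility_deficit: float = 0.15  # subtracted from mobility_mean
    hospital_room_factor: float = 0.8  # resident-room MAD multiplier, hospital group
    beacon_noise_sd_dbm: float = 4.0
    rssi_at_1m_dbm: float = -45.0
    path_loss_exponent: float = 2.0
    near_distance_m: float = 2.0
    far_distance_m: float = 12.0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients: must be >= 1")
        for name in ("p_hospital", "p_missing_day", "walking_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: probability {v} outside [0, 1]")
        if self.walking_fraction >= 0.01:
            raise ConfigurationError(
                "walking_fraction: must be < 0.01 (sedentary-dominant cohort)"
            )
        if self.n_days < 1:
            raise ConfigurationError("n_days: must be >= 1")
        if self.wear_seconds <= 0:
            raise ConfigurationError("wear_end: wear window must have positive duration")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz: must be > 0")
        if self.mode not in ("raw", "window"):
            raise ConfigurationError(f"mode: {self.mode!r} not in {{'raw', 'window'}}")
        if self.window_duration_s <= 0:
            raise ConfigurationError("window_duration_s: must be > 0")
        if self.therapy_minutes_per_day < 0:
            raise ConfigurationError("therapy_minutes_per_day: must be >= 0")
        if set(self.activity_mad_means) != set(ACTIVITIES):
            raise ConfigurationError(
                f"activity_mad_means: keys must be {set(ACTIVITIES)}"
            )
        if any(v <= 0 for v in self.activity_mad_means.values()):
            raise ConfigurationError("activity_mad_means: baselines must be > 0")
        if self.score_noise_sd < 0:
            raise ConfigurationError("score_noise_sd: must be >= 0")
        locations = set(self.beacon_map_spec.values())
        missing = REQUIRED_LOCATIONS - locations
        if missing:
            raise ConfigurationError(
                f"beacon_map_spec: facility map lacks locations {sorted(missing)}"
            )
        if any(d < 0 for d in self.assessment_days):
            raise ConfigurationError("assessment_days: offsets must be >= 0")

    # ------------------------------------------------------------------
    @property
    def wear_start_s(self) -> int:
        return _parse_clock(self.wear_start, "wear_start")

    @property
    def wear_seconds(self) -> int:
        """Duration of the daily wear window in seconds."""
        return _parse_clock(self.wear_end, "wear_end") - _parse_clock(
            self.wear_start, "wear_start"
        )

    @property
    def n_slots(self) -> int:
        """Number of whole analysis windows per wear day."""
        return int(self.wear_seconds // self.window_duration_s)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort analysis filters."""

    min_valid_days: int = 3
    min_wear_hours_per_day: float = 4.0
    min_sessions: int = 3
    max_merge_gap_days: int = 3

    def __post_init__(self) -> None:
        for name in (
            "min_valid_days",
            "min_wear_hours_per_day",
            "min_sessions",
            "max_merge_gap_days",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be positive")


def load_config(path) -> tuple[SimulationConfig, InclusionCriteria]:
    """Load a YAML/JSON config file mirroring SimulationConfig + InclusionCriteria.

    Top-level keys ``simulation`` and ``inclusion`` are each optional; missing
    fields take their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = dict(raw.get("simulation", {}))
    if "assessment_days" in sim_kwargs:
        sim_kwargs["assessment_days"] = tuple(sim_kwargs["assessment_days"])
    sim = SimulationConfig(**sim_kwargs)
    inc = InclusionCriteria(**raw.get("inclusion", {}))
    return sim, inc
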