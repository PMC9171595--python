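"""Synthetic skilled-nursing-facility cohort generator.

Emulates a remote-monitoring study in which every patient wears a smartwatch
from 09:00 to 18:00, spends about one scheduled hour per day in the therapy
area, is otherwise overwhelmingly sedentary in the resident room (walking on
the order of 0.2% of wear time), and receives weekly PT/OT assessment
batteries over a rehabilitation course of at most 21 days.

Each patient carries a latent mobility scale: a baseline level plus a linear
per-week drift, positive for patients discharged to the community and
non-positive for patients readmitted to hospital. The latent scale multiplies
the per-activity movement-intensity (MAD) baselines and drives the weekly
assessment scores, so sensor features and clinical outcomes share a common
longitudinal signal — the structure the downstream mixed models estimate.

Two generation modes:

* ``window`` — directly emits per-10-s-window MAD values with ground-truth
  activity and location labels: fast enough for cohort-scale (110 x 21 day)
  pipeline runs.
* ``raw`` — synthesizes triaxial 25 Hz samples and per-second beacon RSSI
  pings for signal-level tests. Standing windows carry a low-frequency
  postural-sway component and walking windows a ~1.8 Hz gait component, so
  spectral features are class-informative as they are for real wrist signals.

All interval boundaries are aligned to the analysis window length, so the
ground-truth intervals tile the wear window exactly and truth-bypass time
budgets are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ACTIVITIES, SimulationConfig
from .errors import ConfigurationError, IntegrityError
from .signal_features import FEATURE_ORDER, mad as _mad, magnitude, window_features

_G = 9.81  # gravity, m/s^2
_G_CLIP = 2 * _G  # +/- 2 g accelerometer range
_SQRT_HALF_PI = float(np.sqrt(np.pi / 2.0))

_LOCATIONS = ("resident_room", "therapy_area", "bathroom")
_ACT_CODE = {a: i for i, a in enumerate(ACTIVITIES)}
_LOC_CODE = {loc: i for i, loc in enumerate(_LOCATIONS)}

# Resident-room activity mix (stationary bout distribution). Chosen with the
# fixed per-activity MAD baselines so the cohort median overall energy
# intensity lands in the mid-teens on the kappa=1000 reporting scale.
_ROOM_ACT_PROBS = np.array([0.25, 0.40, 0.35])  # laying, sitting, standing
_ROOM_BOUT_MEAN_SLOTS = 60  # ~10 min mean stationary bout
_BATHROOM_VISITS_MEAN = 4.0
_WALK_SLOTS_LO, _WALK_SLOTS_HI = 4, 9  # walking slots/day: uniform {4..8}


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient with their latent mobility trajectory."""

    patient_id: str
    age: float
    sex: str
    race: str
    outcome_group: str  # {"community", "hospital"}
    enrollment_day: int
    latent_mobility_0: float
    latent_slope: float  # per-week latent drift

    def mobility(self, day_index: float) -> float:
        """Latent mobility multiplier on the given day (week = day/7)."""
        return float(
            np.clip(self.latent_mobility_0 + self.latent_slope * day_index / 7.0, 0.3, 2.5)
        )


@dataclass(frozen=True)
class GroundTruthInterval:
    """Truth activity/location label over [start_s, end_s) of one wear day."""

    patient_id: str
    day_index: int
    start_s: float
    end_s: float
    activity: str
    location: str


@dataclass
class CohortDataset:
    """Everything one simulation run produced."""

    config: SimulationConfig
    facility_map: dict[str, str]
    patients: pd.DataFrame
    truth_intervals: pd.DataFrame
    assessments: pd.DataFrame
    windows: Optional[pd.DataFrame] = None  # window mode
    accel: Optional[pd.DataFrame] = None  # raw mode
    beacons: Optional[pd.DataFrame] = None  # raw mode
    missing_days: pd.DataFrame = field(default_factory=pd.DataFrame)

    def patient_records(self) -> list[PatientRecord]:
        return [
            PatientRecord(
                patient_id=r.patient_id,
                age=r.age,
                sex=r.sex,
                race=r.race,
                outcome_group=r.outcome_group,
                enrollment_day=int(r.enrollment_day),
                latent_mobility_0=r.latent_mobility_0,
                latent_slope=r.latent_slope,
            )
            for r in self.patients.itertuples(index=False)
        ]

    # ------------------------------------------------------------------
    def write(self, outdir) -> None:
        """Serialize the dataset to CSV/JSON files in ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(outdir / "patients.csv", index=False)
        self.truth_intervals.to_csv(outdir / "truth_intervals.csv", index=False)
        self.assessments.to_csv(outdir / "assessments.csv", index=False)
        if self.windows is not None:
            self.windows.to_csv(outdir / "windows.csv", index=False)
        if self.accel is not None:
            self.accel.to_csv(outdir / "accel.csv", index=False)
        if self.beacons is not None:
            self.beacons.to_csv(outdir / "beacons.csv", index=False)
        if len(self.missing_days):
            self.missing_days.to_csv(outdir / "missing_days.csv", index=False)
        with open(outdir / "facility_map.json", "w") as fh:
            json.dump(self.facility_map, fh, indent=2, sort_keys=True)


# ----------------------------------------------------------------------
# Day scheduling
# ----------------------------------------------------------------------

def _fill_stationary_bouts(act: np.ndarray, start: int, stop: int, rng) -> None:
    """Fill act[start:stop] with laying/sitting/standing bouts."""
    pos = start
    while pos < stop:
        a = int(rng.choice(3, p=_ROOM_ACT_PROBS))
        length = int(rng.geometric(1.0 / _ROOM_BOUT_MEAN_SLOTS))
        act[pos : min(pos + length, stop)] = a
        pos += length


def build_day_schedule(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Activity and location codes per analysis slot for one wear day.

    Returns (activity_codes, location_codes), each of length config.n_slots.
    Codes index ACTIVITIES and the internal location order
    (resident_room, therapy_area, bathroom).
    """
    n = config.n_slots
    loc = np.zeros(n, dtype=np.int8)  # resident_room

    # One scheduled therapy block, duration jittered within +/-8%.
    dur = int(round(config.therapy_minutes_per_day * 60.0 / config.window_duration_s
                    * rng.uniform(0.92, 1.08)))
    dur = min(dur, n)
    if dur > 0:
        start = int(rng.integers(0, n - dur + 1))
        loc[start : start + dur] = _LOC_CODE["therapy_area"]

    # Short bathroom visits outside the therapy block.
    for _ in range(int(rng.poisson(_BATHROOM_VISITS_MEAN))):
        d = int(rng.integers(3, 31))  # 30 s .. 5 min
        if n - d <= 0:
            continue
        s = int(rng.integers(0, n - d))
        if np.any(loc[s : s + d] != _LOC_CODE["resident_room"]):
            continue
        loc[s : s + d] = _LOC_CODE["bathroom"]

    act = np.empty(n, dtype=np.int8)
    # Resident-room runs: stationary bouts with the room mix.
    # Therapy: alternating sitting/standing efforts. Bathroom: standing.
    boundaries = np.flatnonzero(np.diff(loc)) + 1
    run_starts = np.concatenate(([0], boundaries))
    run_stops = np.concatenate((boundaries, [n]))
    for a, b in zip(run_starts, run_stops):
        code = loc[a]
        if code == _LOC_CODE["resident_room"]:
            _fill_stationary_bouts(act, a, b, rng)
        elif code == _LOC_CODE["therapy_area"]:
            pos = a
            current = int(rng.integers(1, 3))  # sitting or standing
            while pos < b:
                length = int(rng.integers(12, 48))  # 2..8 min efforts
                act[pos : min(pos + length, b)] = current
                current = 3 - current  # toggle sitting<->standing
                pos += length
        else:  # bathroom
            act[a:b] = _ACT_CODE["standing"]

    # Sparse walking bouts override the stationary label wherever they land.
    remaining = int(rng.integers(_WALK_SLOTS_LO, _WALK_SLOTS_HI))
    while remaining > 0:
        bout = min(int(rng.integers(1, 4)), remaining, n)
        pos = int(rng.integers(0, n - bout + 1))
        act[pos : pos + bout] = _ACT_CODE["walking"]
        remaining -= bout
    return act, loc


def _runs_to_intervals(
    act: np.ndarray, loc: np.ndarray, window_s: float
) -> list[tuple[float, float, str, str]]:
    """Run-length encode joint (activity, location) codes into intervals."""
    n = len(act)
    if n == 0:
        return []
    change = np.flatnonzero((np.diff(act) != 0) | (np.diff(loc) != 0)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n]))
    return [
        (s * window_s, e * window_s, ACTIVITIES[act[s]], _LOCATIONS[loc[s]])
        for s, e in zip(starts, stops)
    ]


# ----------------------------------------------------------------------
# Raw-signal synthesis
# ----------------------------------------------------------------------

def _zero_mean_component(activity: str, target_mad: float, n: int,
                         sample_rate_hz: float, rng) -> np.ndarray:
    """Zero-mean vertical-axis fluctuation with MAD calibrated to target_mad."""
    t = np.arange(n) / sample_rate_hz
    if activity in ("laying", "sitting"):
        comp = rng.normal(0.0, target_mad * _SQRT_HALF_PI, n)
    elif activity == "standing":
        # Postural sway: slow oscillation plus broadband fidgeting.
        f = rng.uniform(0.3, 0.8)
        amp = 0.6 * target_mad * np.pi / 2.0
        comp = amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        comp = comp + rng.normal(0.0, 0.4 * target_mad * _SQRT_HALF_PI, n)
    else:  # walking: dominant gait frequency
        f = rng.uniform(1.5, 2.1)
        amp = 0.7 * target_mad * np.pi / 2.0
        comp = amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        comp = comp + rng.normal(0.0, 0.3 * target_mad * _SQRT_HALF_PI, n)
    # Rescale so the realized fluctuation MAD matches the target.
    comp = comp - comp.mean()
    realized = np.mean(np.abs(comp))
    if realized > 0:
        comp *= target_mad / realized
    return comp


def _synth_window_axes(activity: str, target_mad: float, n: int,
                       sample_rate_hz: float, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triaxial samples for one window; gravity on z, fluctuation calibrated."""
    comp = _zero_mean_component(activity, target_mad, n, sample_rate_hz, rng)
    ax = rng.normal(0.0, 0.3 * target_mad, n)
    ay = rng.normal(0.0, 0.3 * target_mad, n)
    az = _G + comp
    return (
        np.clip(ax, -_G_CLIP, _G_CLIP),
        np.clip(ay, -_G_CLIP, _G_CLIP),
        np.clip(az, -_G_CLIP, _G_CLIP),
    )


def _check_tiling(intervals) -> None:
    prev_end = None
    for iv in intervals:
        if iv.end_s <= iv.start_s:
            raise IntegrityError(f"empty/negative interval at {iv.start_s}")
        if prev_end is not None and iv.start_s < prev_end:
            raise IntegrityError(f"overlapping intervals at {iv.start_s}")
        prev_end = iv.end_s


def synthesize_accel_stream(
    intervals: list[GroundTruthInterval],
    config: SimulationConfig,
    rng,
    mobility: float = 1.0,
) -> pd.DataFrame:
    """Triaxial samples (t_s, ax, ay, az in m/s^2) realizing the truth intervals.

    Window-by-window, the magnitude MAD concentrates near
    ``activity_mad_means[activity] * mobility`` with lognormal window jitter;
    samples are clipped to the +/- 2 g hardware range.
    """
    _check_tiling(intervals)
    rate = config.sample_rate_hz
    wlen = config.window_duration_s
    t_parts, x_parts, y_parts, z_parts = [], [], [], []
    for iv in intervals:
        base = config.activity_mad_means[iv.activity] * mobility
        pos = iv.start_s
        while pos < iv.end_s:
            stop = min(pos + wlen, iv.end_s)
            n = int(round((stop - pos) * rate))
            if n == 0:
                break
            target = base * rng.lognormal(0.0, config.mad_window_sigma)
            ax, ay, az = _synth_window_axes(iv.activity, target, n, rate, rng)
            t_parts.append(pos + np.arange(n) / rate)
            x_parts.append(ax)
            y_parts.append(ay)
            z_parts.append(az)
            pos = stop
    if not t_parts:
        return pd.DataFrame(columns=["t_s", "ax", "ay", "az"])
    return pd.DataFrame(
        {
            "t_s": np.concatenate(t_parts),
            "ax": np.concatenate(x_parts),
            "ay": np.concatenate(y_parts),
            "az": np.concatenate(z_parts),
        }
    )


def synthesize_beacon_stream(
    intervals: list[GroundTruthInterval],
    beacon_map: dict[str, str],
    config: SimulationConfig,
    rng,
) -> pd.DataFrame:
    """Per-second RSSI pings (t_s, beacon_id, rssi_dbm) from every beacon.

    Log-distance path-loss model: the beacon co-located with the current truth
    location is near (strong), all others far (weak), plus Gaussian shadowing
    noise. Raises ConfigurationError for a truth location with no beacon.
    """
    known_locations = set(beacon_map.values())
    beacon_ids = sorted(beacon_map)
    p0 = config.rssi_at_1m_dbm
    ple = config.path_loss_exponent
    rssi_near = p0 - 10.0 * ple * np.log10(config.near_distance_m)
    rssi_far = p0 - 10.0 * ple * np.log10(config.far_distance_m)

    t_parts, b_parts, r_parts = [], [], []
    for iv in intervals:
        if iv.location not in known_locations:
            raise ConfigurationError(
                f"beacon_map_spec: no beacon at location {iv.location!r}"
            )
        seconds = np.arange(int(np.ceil(iv.start_s)), int(np.ceil(iv.end_s)), dtype=float)
        if seconds.size == 0:
            continue
        for b in beacon_ids:
            base = rssi_near if beacon_map[b] == iv.location else rssi_far
            noise = (
                rng.normal(0.0, config.beacon_noise_sd_dbm, seconds.size)
                if config.beacon_noise_sd_dbm > 0
                else np.zeros(seconds.size)
            )
            t_parts.append(seconds)
            b_parts.append(np.full(seconds.size, b, dtype=object))
            r_parts.append(base + noise)
    if not t_parts:
        return pd.DataFrame(columns=["t_s", "beacon_id", "rssi_dbm"])
    df = pd.DataFrame(
        {
            "t_s": np.concatenate(t_parts),
            "beacon_id": np.concatenate(b_parts),
            "rssi_dbm": np.concatenate(r_parts),
        }
    )
    return df.sort_values(["t_s", "beacon_id"], kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# Clinical assessments
# ----------------------------------------------------------------------

#: Functional-level measures: measure -> (discipline, baseline mean level).
FUNCTIONAL_LEVEL_MEASURES: dict[str, tuple[str, float]] = {
    "transfer_general": ("PT", 3.4),
    "gait_level_surfaces": ("PT", 3.6),
    "bed_mobility_supine_sit": ("PT", 3.5),
    "dressing_lower_body": ("OT", 3.2),
    "toileting_general": ("OT", 3.5),
    "hygiene_grooming": ("OT", 3.8),
}

#: Latent-mobility gain on the 1-6 functional-level scale.
_LEVEL_GAIN = 5.0
#: Gait-distance model (feet): intercept + per-week gain scaled to latent slope.
_GAIT_BASE_FT, _GAIT_SLOPE_FT_PER_LATENT = 40.0, 1400.0
_GAIT_BASELINE_GAIN_FT = 150.0
#: Activity-tolerance model (minutes).
_TOL_BASE_MIN, _TOL_SLOPE_MIN_PER_LATENT = 8.0, 100.0
_TOL_BASELINE_GAIN_MIN = 20.0


def generate_assessments(
    patient: PatientRecord, config: SimulationConfig, rng
) -> pd.DataFrame:
    """Weekly PT and OT batteries for one patient.

    Functional levels are integers 1-6 with higher = more independent; they
    track the patient's latent mobility, so community patients (positive
    latent slope) improve on average week over week. Gait distance (feet) and
    activity tolerance (minutes) are continuous, nonnegative, and share the
    same latent drift.
    """
    rows = []
    lm0_centered = patient.latent_mobility_0 - config.mobility_mean
    for day in config.assessment_days:
        if day > config.n_days:
            continue
        t_w = day / 7.0
        mob = patient.mobility(day)
        for measure, (disc, base) in FUNCTIONAL_LEVEL_MEASURES.items():
            level = base + _LEVEL_GAIN * (mob - 1.0) + rng.normal(0.0, config.score_noise_sd)
            rows.append((patient.patient_id, day, disc, measure,
                         float(np.clip(round(level), 1, 6))))
        # Assistive-device score: stable around 2 (walker + wheelchair cohort).
        dev = 2.0 + rng.normal(0.0, 0.5 * config.score_noise_sd)
        rows.append((patient.patient_id, day, "PT", "gait_assistive_device",
                     float(np.clip(round(dev), 1, 6))))
        gait = (_GAIT_BASE_FT
                + _GAIT_SLOPE_FT_PER_LATENT * patient.latent_slope * t_w
                + _GAIT_BASELINE_GAIN_FT * lm0_centered
                + rng.normal(0.0, 30.0 * config.score_noise_sd))
        rows.append((patient.patient_id, day, "PT", "gait_distance_feet",
                     round(max(0.0, gait), 1)))
        tol = (_TOL_BASE_MIN
               + _TOL_SLOPE_MIN_PER_LATENT * patient.latent_slope * t_w
               + _TOL_BASELINE_GAIN_MIN * lm0_centered
               + rng.normal(0.0, 4.0 * config.score_noise_sd))
        rows.append((patient.patient_id, day, "OT", "activity_tolerance_general",
                     round(max(0.0, tol), 1)))
    return pd.DataFrame(
        rows, columns=["patient_id", "day_index", "discipline", "measure", "value"]
    )


# ----------------------------------------------------------------------
# Cohort assembly
# ----------------------------------------------------------------------

_RACES = ("White", "Black or African American", "Asian",
          "Hispanic or Latino", "Native Hawaiian or Pacific Islander")
_RACE_PROBS = (0.76, 0.12, 0.05, 0.04, 0.03)


def _generate_patients(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_patients
    width = max(3, len(str(n)))
    ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    hospital = rng.random(n) < config.p_hospital
    age = np.clip(rng.normal(79.4, 5.9, n), 61.0, 99.0).round(1)
    sex = np.where(rng.random(n) < 0.72, "female", "male")
    race = rng.choice(_RACES, size=n, p=_RACE_PROBS)
    lm0 = rng.normal(
        config.mobility_mean - config.hospital_mobility_deficit * hospital,
        config.mobility_sd,
    )
    lm0 = np.clip(lm0, 0.4, 2.0)
    slope = np.where(
        hospital, config.latent_slope_hospital, config.latent_slope_community
    )
    return pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "sex": sex,
            "race": race,
            "outcome_group": np.where(hospital, "hospital", "community"),
            "enrollment_day": 0,
            "latent_mobility_0": lm0,
            "latent_slope": slope,
        }
    )


def _day_window_mads(
    act: np.ndarray,
    loc: np.ndarray,
    config: SimulationConfig,
    mobility: float,
    is_hospital: bool,
    rng,
) -> np.ndarray:
    """Per-slot MAD values for one day (window mode)."""
    base = np.array([config.activity_mad_means[a] for a in ACTIVITIES])
    mads = base[act] * mobility
    if is_hospital and config.hospital_room_factor != 1.0:
        mads = np.where(
            loc == _LOC_CODE["resident_room"],
            mads * config.hospital_room_factor,
            mads,
        )
    jitter = rng.lognormal(0.0, config.mad_window_sigma, size=len(act))
    return mads * jitter


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a full synthetic cohort, deterministically from config.seed.

    In window mode the dataset carries a ``windows`` table (per-window MAD
    with truth activity/location labels); in raw mode it carries ``accel``
    and ``beacons`` sample tables. Ground-truth intervals tile each wear
    window exactly in both modes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _generate_patients(config, rng)
    facility_map = dict(config.beacon_map_spec)
    wlen = config.window_duration_s
    n_slots = config.n_slots

    truth_rows: list[tuple] = []
    missing_rows: list[tuple] = []
    assess_frames: list[pd.DataFrame] = []

    window_mode = config.mode == "window"
    if window_mode:
        w_pid: list[np.ndarray] = []
        w_day: list[np.ndarray] = []
        w_start: list[np.ndarray] = []
        w_mad: list[np.ndarray] = []
        w_act: list[np.ndarray] = []
        w_loc: list[np.ndarray] = []
    else:
        accel_frames: list[pd.DataFrame] = []
        beacon_frames: list[pd.DataFrame] = []

    records = CohortDataset(
        config, facility_map, patients, pd.DataFrame(), pd.DataFrame()
    ).patient_records()

    for p_idx, patient in enumerate(records):
        is_hospital = patient.outcome_group == "hospital"
        for day in range(config.n_days):
            if rng.random() < config.p_missing_day:
                missing_rows.append((patient.patient_id, day))
                continue
            act, loc = build_day_schedule(config, rng)
            for s, e, a, lo in _runs_to_intervals(act, loc, wlen):
                truth_rows.append((patient.patient_id, day, s, e, a, lo))
            mobility = patient.mobility(day)
            if window_mode:
                mads = _day_window_mads(act, loc, config, mobility, is_hospital, rng)
                w_pid.append(np.full(n_slots, p_idx, dtype=np.int32))
                w_day.append(np.full(n_slots, day, dtype=np.int32))
                w_start.append(np.arange(n_slots, dtype=np.float64) * wlen)
                w_mad.append(mads)
                w_act.append(act.copy())
                w_loc.append(loc.copy())
            else:
                ivs = [
                    GroundTruthInterval(patient.patient_id, day, s, e, a, lo)
                    for s, e, a, lo in _runs_to_intervals(act, loc, wlen)
                ]
                room_factor = (
                    config.hospital_room_factor if is_hospital else 1.0
                )
                acc_parts = []
                for iv in ivs:
                    mob = mobility * (
                        room_factor if iv.location == "resident_room" else 1.0
                    )
                    acc_parts.append(
                        synthesize_accel_stream([iv], config, rng, mobility=mob)
                    )
                acc = pd.concat(acc_parts, ignore_index=True) if acc_parts else None
                if acc is not None and len(acc):
                    acc.insert(0, "patient_id", patient.patient_id)
                    acc.insert(1, "day_index", day)
                    accel_frames.append(acc)
                bea = synthesize_beacon_stream(ivs, facility_map, config, rng)
                if len(bea):
                    bea.insert(0, "patient_id", patient.patient_id)
                    bea.insert(1, "day_index", day)
                    beacon_frames.append(bea)
        assess_frames.append(generate_assessments(patient, config, rng))

    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "day_index", "start_s", "end_s", "activity", "location"],
    )
    assessments = (
        pd.concat(assess_frames, ignore_index=True)
        if assess_frames
        else pd.DataFrame(columns=["patient_id", "day_index", "discipline", "measure", "value"])
    )
    missing = pd.DataFrame(missing_rows, columns=["patient_id", "day_index"])

    dataset = CohortDataset(
        config=config,
        facility_map=facility_map,
        patients=patients,
        truth_intervals=truth,
        assessments=assessments,
        missing_days=missing,
    )
    if window_mode:
        if w_pid:
            pid_codes = np.concatenate(w_pid)
            dataset.windows = pd.DataFrame(
                {
                    "patient_id": pd.Categorical.from_codes(
                        pid_codes, categories=patients["patient_id"].tolist()
                    ),
                    "day_index": np.concatenate(w_day),
                    "window_start_s": np.concatenate(w_start),
                    "duration_s": wlen,
                    "mad": np.concatenate(w_mad),
                    "activity": pd.Categorical.from_codes(
                        np.concatenate(w_act), categories=list(ACTIVITIES)
                    ),
                    "location": pd.Categorical.from_codes(
                        np.concatenate(w_loc), categories=list(_LOCATIONS)
                    ),
                    "worn": True,
                }
            )
        else:
            dataset.windows = pd.DataFrame(
                columns=["patient_id", "day_index", "window_start_s", "duration_s",
                         "mad", "activity", "location", "worn"]
            )
    else:
        dataset.accel = (
            pd.concat(accel_frames, ignore_index=True)
            if accel_frames
            else pd.DataFrame(columns=["patient_id", "day_index", "t_s", "ax", "ay", "az"])
        )
        dataset.beacons = (
            pd.concat(beacon_frames, ignore_index=True)
            if beacon_frames
            else pd.DataFrame(
                columns=["patient_id", "day_index", "t_s", "beacon_id", "rssi_dbm"]
            )
        )
    return dataset


# ----------------------------------------------------------------------
# Classifier training material
# ----------------------------------------------------------------------

def sample_regime_windows(
    config: SimulationConfig, n_per_class: int, seed: int
) -> pd.DataFrame:
    """Feature vectors of raw-signal windows drawn from each activity regime.

    Each window gets an independent latent-mobility draw (between-patient
    spread) and lognormal window jitter, mirroring the cohort generator.
    Returns one row per window with FEATURE_ORDER columns plus ``activity``.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(config.sample_rate_hz * config.window_duration_s))
    rows = []
    for activity in ACTIVITIES:
        base = config.activity_mad_means[activity]
        for _ in range(n_per_class):
            mobility = max(0.3, rng.normal(config.mobility_mean, config.mobility_sd))
            target = base * mobility * rng.lognormal(0.0, config.mad_window_sigma)
            ax, ay, az = _synth_window_axes(
                activity, target, n_samples, config.sample_rate_hz, rng
            )
            m = magnitude(ax, ay, az)
            feats = window_features(m, config.sample_rate_hz)
            rows.append(
                (_mad(m), feats.mean, feats.median, feats.variance, feats.skewness,
                 feats.kurtosis, feats.peak_frequency, feats.peak_power, activity)
            )
    return pd.DataFrame(rows, columns=list(FEATURE_ORDER) + ["activity"])
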