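"""Cohort generator: schedules, streams, assessments, determinism."""

import numpy as np
import pandas as pd
import pytest

from wardsense import (
    GroundTruthInterval,
    PatientRecord,
    SimulationConfig,
    generate_assessments,
    generate_cohort,
    synthesize_accel_stream,
    synthesize_beacon_stream,
)
from wardsense.errors import ConfigurationError
from wardsense.signal_features import mad, magnitude, window_stream


def _patient(pid="P1", group="community", lm0=1.05, slope=0.04):
    return PatientRecord(
        patient_id=pid, age=80.0, sex="female", race="White",
        outcome_group=group, enrollment_day=0,
        latent_mobility_0=lm0, latent_slope=slope,
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [("n_patients", 0),
         ("p_hospital", 1.5),
         ("walking_fraction", 0.02),
         ("n_days", 0),
         ("mode", "streaming"),
         ("score_noise_sd", -1.0)],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**{field: value})

    def test_activity_keys_checked(self):
        with pytest.raises(ConfigurationError, match="activity_mad_means"):
            SimulationConfig(activity_mad_means={"sitting": 0.01})

    def test_facility_map_must_cover_required_locations(self):
        with pytest.raises(ConfigurationError, match="beacon_map_spec"):
            SimulationConfig(beacon_map_spec={"b1": "resident_room"})


class TestSchedules:
    def test_single_day_tiles_wear_window(self):
        cfg = SimulationConfig(n_patients=4, n_days=1, p_missing_day=0.0, seed=3)
        ds = generate_cohort(cfg)
        for pid, grp in ds.truth_intervals.groupby("patient_id"):
            grp = grp.sort_values("start_s")
            assert grp["day_index"].nunique() == 1
            assert grp["start_s"].iloc[0] == 0.0
            assert grp["end_s"].iloc[-1] == cfg.wear_seconds  # 09:00-18:00
            assert np.allclose(grp["end_s"].iloc[:-1].values,
                               grp["start_s"].iloc[1:].values)
            assert (grp["end_s"] > grp["start_s"]).all()

    def test_truth_tiling_sums_to_wear_duration(self, small_cohort, small_config):
        durs = (
            small_cohort.truth_intervals.assign(
                d=lambda f: f["end_s"] - f["start_s"]
            ).groupby(["patient_id", "day_index"])["d"].sum()
        )
        assert (durs == small_config.wear_seconds).all()

    def test_therapy_time_near_scheduled_hour(self, small_cohort, small_config):
        w = small_cohort.windows
        ther = (
            w[w["location"] == "therapy_area"]
            .groupby(["patient_id", "day_index"], observed=True)["duration_s"]
            .sum()
        )
        target = small_config.therapy_minutes_per_day * 60.0
        assert ((ther >= 0.8 * target) & (ther <= 1.2 * target)).all()

    def test_missing_days_absent_everywhere(self):
        cfg = SimulationConfig(n_patients=6, n_days=10, p_missing_day=0.3, seed=9)
        ds = generate_cohort(cfg)
        assert len(ds.missing_days) > 0
        present = set(map(tuple, ds.windows[["patient_id", "day_index"]]
                          .drop_duplicates().astype(str).values))
        for pid, day in ds.missing_days.itertuples(index=False):
            assert (str(pid), str(day)) not in present

    def test_outcome_split_matches_expected_rate(self):
        ds = generate_cohort(SimulationConfig(n_patients=110, p_hospital=5 / 110, seed=1))
        n_hosp = (ds.patients["outcome_group"] == "hospital").sum()
        # E[n_hosp] = 5; 0..13 covers >99.9% of Binomial(110, 5/110)
        assert 0 <= n_hosp <= 13
        assert set(ds.patients["outcome_group"]) <= {"community", "hospital"}


class TestDeterminism:
    def test_identical_seed_byte_identical_output(self, tmp_path):
        cfg = SimulationConfig(n_patients=5, n_days=4, seed=21)
        for d in ("a", "b"):
            generate_cohort(cfg).write(tmp_path / d)
        for name in ("patients.csv", "windows.csv", "truth_intervals.csv",
                     "assessments.csv", "facility_map.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()


class TestAccelStream:
    def _laying_intervals(self, n_windows=60):
        return [GroundTruthInterval("P1", 0, 0.0, n_windows * 10.0,
                                    "laying", "resident_room")]

    def test_laying_mads_concentrate_near_baseline(self):
        cfg = SimulationConfig(mode="raw", n_patients=1)
        rng = np.random.default_rng(0)
        acc = synthesize_accel_stream(self._laying_intervals(100), cfg, rng)
        m = magnitude(acc["ax"], acc["ay"], acc["az"])
        wins = window_stream(acc["t_s"].to_numpy(), m, cfg.sample_rate_hz,
                             compute_features=False)
        mads = np.array([w.mad for w in wins if w.worn])
        frac = np.mean((mads >= 0.002) & (mads <= 0.010))
        assert frac >= 0.95

    def test_samples_within_hardware_range(self):
        cfg = SimulationConfig(mode="raw", n_patients=1)
        rng = np.random.default_rng(1)
        iv = [GroundTruthInterval("P1", 0, 0.0, 600.0, "walking", "therapy_area")]
        acc = synthesize_accel_stream(iv, cfg, rng)
        for col in ("ax", "ay", "az"):
            assert acc[col].abs().max() <= 2 * 9.81 + 1e-9

    def test_zero_duration_day_empty(self):
        cfg = SimulationConfig(mode="raw", n_patients=1)
        acc = synthesize_accel_stream([], cfg, np.random.default_rng(0))
        assert len(acc) == 0

    def test_walking_mad_exceeds_three_times_sitting(self):
        cfg = SimulationConfig(mode="raw", n_patients=1)
        rng = np.random.default_rng(2)
        out = {}
        for act in ("sitting", "walking"):
            iv = [GroundTruthInterval("P1", 0, 0.0, 600.0, act, "resident_room")]
            acc = synthesize_accel_stream(iv, cfg, rng)
            m = magnitude(acc["ax"], acc["ay"], acc["az"])
            wins = window_stream(acc["t_s"].to_numpy(), m, cfg.sample_rate_hz,
                                 compute_features=False)
            out[act] = np.median([w.mad for w in wins if w.worn])
        assert out["walking"] > 3.0 * out["sitting"]


class TestBeaconStream:
    def test_noiseless_colocated_beacon_strictly_strongest(self):
        cfg = SimulationConfig(beacon_noise_sd_dbm=0.0)
        iv = [GroundTruthInterval("P1", 0, 0.0, 60.0, "sitting", "therapy_area")]
        pings = synthesize_beacon_stream(iv, dict(cfg.beacon_map_spec), cfg,
                                         np.random.default_rng(0))
        assert pings["t_s"].nunique() == 60
        for _, sec in pings.groupby("t_s"):
            best = sec.loc[sec["rssi_dbm"].idxmax(), "beacon_id"]
            assert dict(cfg.beacon_map_spec)[best] == "therapy_area"

    def test_empty_interval_list(self):
        cfg = SimulationConfig()
        pings = synthesize_beacon_stream([], dict(cfg.beacon_map_spec), cfg,
                                         np.random.default_rng(0))
        assert len(pings) == 0

    def test_unknown_location_rejected(self):
        cfg = SimulationConfig()
        iv = [GroundTruthInterval("P1", 0, 0.0, 60.0, "sitting", "garden")]
        with pytest.raises(ConfigurationError, match="garden"):
            synthesize_beacon_stream(iv, dict(cfg.beacon_map_spec), cfg,
                                     np.random.default_rng(0))


class TestAssessments:
    def test_four_sessions_over_21_day_stay(self):
        cfg = SimulationConfig(n_days=21)
        df = generate_assessments(_patient(), cfg, np.random.default_rng(0))
        assert df["day_index"].nunique() == 4  # days 0, 7, 14, 21
        assert set(df["discipline"]) == {"PT", "OT"}

    def test_functional_levels_in_range(self):
        cfg = SimulationConfig()
        df = generate_assessments(_patient(), cfg, np.random.default_rng(1))
        levels = df.loc[~df["measure"].isin(
            ["gait_distance_feet", "activity_tolerance_general"]), "value"]
        assert levels.between(1, 6).all()
        assert (df["value"] >= 0).all()

    def test_zero_slope_zero_noise_scores_constant(self):
        cfg = SimulationConfig(score_noise_sd=0.0)
        p = _patient(slope=0.0)
        df = generate_assessments(p, cfg, np.random.default_rng(2))
        for _, grp in df.groupby("measure"):
            assert grp["value"].nunique() == 1

    def test_community_gait_distance_improves_by_week_two(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(3)
        frames = []
        for i in range(100):
            lm0 = float(rng.normal(cfg.mobility_mean, cfg.mobility_sd))
            frames.append(generate_assessments(
                _patient(pid=f"P{i}", lm0=lm0), cfg, rng))
        df = pd.concat(frames)
        gait = df[df["measure"] == "gait_distance_feet"]
        med0 = gait.loc[gait["day_index"] == 0, "value"].median()
        med2 = gait.loc[gait["day_index"] == 14, "value"].median()
        assert med2 > med0
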