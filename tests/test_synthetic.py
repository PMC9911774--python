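"""Simulator: stance waveform calibration, truth annotation, artifacts."""

import numpy as np
import pandas as pd
import pytest

from conftest import noise_free_profile, truth_times
from runkin import gait_events as ge
from runkin import kinetics as kin
from runkin import signal_io as sio
from runkin import synthetic_data as sd


class TestStanceWaveform:
    def test_degenerate_single_bell_peak_is_active_amplitude(self):
        shape = sd.StanceShapeParams(impact_amplitude=0.0)
        st = sd.simulate_grf_stance(3.0, "level", 0.28, shape)
        assert st.force[0] == 0.0 and st.force[-1] == 0.0
        assert np.isclose(kin.peak_force(st), shape.active_amplitude, rtol=1e-6)

    def test_default_level_3ms_calibration_envelope(self):
        st = sd.simulate_grf_stance(3.0, "level", 0.28)
        assert 1.1 <= kin.stance_average(st) <= 1.5
        assert 2.0 <= kin.peak_force(st) <= 2.5

    def test_full_width_bell_mean_is_half_amplitude(self):
        # independent oracle: numerical integration of the raised cosine
        A = 2.0
        shape = sd.StanceShapeParams(impact_amplitude=0.0, active_amplitude=A,
                                     active_center_frac=0.5, active_width_frac=0.5)
        u = np.linspace(0.0, 1.0, 200_001)
        oracle_mean = np.trapezoid(A * 0.5 * (1 + np.cos(np.pi * (u - 0.5) / 0.5)), u)
        assert np.isclose(oracle_mean, A / 2, rtol=1e-8)
        st = sd.simulate_grf_stance(3.0, "level", 0.28, shape, sample_rate=1000)
        assert np.isclose(kin.stance_average(st), A / 2, rtol=5e-3)

    @pytest.mark.parametrize("speed,contact_time", [(-1.0, 0.28), (0.0, 0.28),
                                                    (3.0, 0.0), (3.0, -0.2)])
    def test_invalid_arguments_rejected(self, speed, contact_time):
        with pytest.raises(ValueError):
            sd.simulate_grf_stance(speed, "level", contact_time)

    def test_grade_modulates_impact_amplitude(self):
        u = np.linspace(0, 1, 500)
        shape = sd.StanceShapeParams()
        level = sd.stance_waveform(u, 3.0, "level", shape)
        decline = sd.stance_waveform(u, 3.0, "decline", shape)
        incline = sd.stance_waveform(u, 3.0, "incline", shape)
        early = u < 0.2
        assert decline[early].max() > level[early].max() > incline[early].max()

    @pytest.mark.parametrize("speed", [2.5, 3.0, 3.5, 4.0, 4.5])
    @pytest.mark.parametrize("grade_class", ["level", "incline", "decline"])
    def test_calibration_envelope_across_speeds(self, speed, grade_class):
        profile = sd.SubjectProfile("S")
        st = sd.simulate_grf_stance(speed, grade_class, profile.contact_time(speed))
        assert 1.1 <= kin.stance_average(st) <= 1.7
        assert 2.0 <= kin.peak_force(st) <= 3.0


class TestSimulateSession:
    def test_seed_is_required(self, default_profile):
        with pytest.raises(ValueError):
            sd.simulate_session(default_profile, sd.steady_course(30, 3.0), None)

    def test_determinism_under_fixed_seed(self, default_profile):
        course = sd.steady_course(15.0, 3.2)
        a = sd.simulate_session(default_profile, course, seed=0)
        b = sd.simulate_session(default_profile, course, seed=0)
        assert np.array_equal(a.left_imu.values, b.left_imu.values)
        assert np.array_equal(a.right_force.values, b.right_force.values)
        assert a.truth.equals(b.truth)

    def test_zero_speed_course_is_quiet(self):
        profile = noise_free_profile()
        bundle = sd.simulate_session(
            profile, sd.CourseProfile(segments=((20.0, 0.0, 0.0),)), seed=1)
        assert len(bundle.truth) == 0
        assert np.all(bundle.left_force.values == 0.0)
        assert np.all(bundle.left_imu.values == 0.0)

    def test_ic_count_matches_stride_arithmetic(self, default_profile):
        bundle = sd.simulate_session(default_profile, sd.steady_course(60.0, 3.0),
                                     seed=0)
        stride = sd.stride_time(3.0)
        counted = len(truth_times(bundle, "IC", "left"))
        assert abs(counted - np.floor(60.0 / stride)) <= 1

    def test_truth_crossing_consistency(self, session30_quiet):
        """Force crosses 5 % BW within one sample of every truth annotation."""
        for side in ("left", "right"):
            force = sio.zero_subthreshold(
                sio.normalize_bw(getattr(session30_quiet, f"{side}_force"),
                                 session30_quiet.mass))
            events = ge.detect_events_force(force, side)
            for kind in ("IC", "TO"):
                det = np.array([e.time for e in events if e.kind == kind])
                tru = truth_times(session30_quiet, kind, side)
                assert det.size == tru.size
                assert np.max(np.abs(det - tru)) <= 1.0 / force.sample_rate + 1e-9

    def test_alternating_feet_with_flight(self, session30):
        ics = session30.truth[session30.truth["event"] == "IC"]
        sides = ics.sort_values("time_s")["side"].tolist()
        assert all(a != b for a, b in zip(sides, sides[1:]))
        # flight: each foot's TO precedes the other foot's next IC
        tos = session30.truth[session30.truth["event"] == "TO"]
        merged = pd.concat([ics, tos]).sort_values("time_s")
        kinds = merged["event"].tolist()
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_noiseless_channels_are_deterministic_functions(self):
        profile = noise_free_profile()
        course = sd.steady_course(12.0, 3.0)
        a = sd.simulate_session(profile, course, seed=0)
        b = sd.simulate_session(profile, course, seed=99)  # seed only feeds noise/GPS
        assert np.array_equal(a.left_imu.values, b.left_imu.values)
        assert np.array_equal(a.sacrum_imu.values, b.sacrum_imu.values)


class TestInjectors:
    def test_clock_drift_identity(self, session30):
        out = sd.inject_clock_drift(session30, 0.0, 0.0)
        assert np.array_equal(out.left_imu.timestamps, session30.left_imu.timestamps)

    def test_pure_offset_shifts_imu_only(self, session30):
        out = sd.inject_clock_drift(session30, 0.5, 0.0)
        assert np.allclose(out.left_imu.timestamps,
                           session30.left_imu.timestamps + 0.5)
        assert np.array_equal(out.left_force.timestamps,
                              session30.left_force.timestamps)
        assert np.allclose(out.truth["time_imu_s"] - out.truth["time_s"], 0.5)

    def test_drift_terminal_misalignment(self, session30):
        out = sd.inject_clock_drift(session30, 0.0, 1e-4)
        gap = out.truth["time_imu_s"] - out.truth["time_s"]
        expect = 1e-4 * out.truth["time_s"]
        assert np.allclose(gap, expect, atol=1e-12)

    def test_baseline_drift_zero_magnitude_identity(self, session30):
        out = sd.inject_baseline_drift(session30.left_force, 0.0, onset=5.0)
        assert np.array_equal(out.values, session30.left_force.values)

    def test_baseline_drift_swing_range(self, session30_quiet):
        drifted = sd.inject_baseline_drift(session30_quiet.left_force, 30.0,
                                           onset=10.0)
        t = drifted.timestamps
        swing = (t > 12.0) & (drifted.force - session30_quiet.left_force.force
                              > 1.0)
        base = drifted.force[(t > 12.0) & (session30_quiet.left_force.force == 0)]
        assert base.size > 0
        assert 20.0 - 1e-9 <= base.min() and base.max() <= 40.0 + 1e-9

    def test_baseline_drift_roundtrip_preserves_events(self, session30_quiet):
        """Drift -> correct_baseline -> force events identical to undrifted."""
        mass = session30_quiet.mass
        clean = sio.zero_subthreshold(
            sio.normalize_bw(session30_quiet.left_force, mass))
        ref = ge.detect_events_force(clean, "left")

        drifted = sd.inject_baseline_drift(session30_quiet.left_force, 30.0,
                                           onset=10.0)
        fixed = sio.zero_subthreshold(
            sio.correct_baseline(sio.normalize_bw(drifted, mass)))
        got = ge.detect_events_force(fixed, "left")
        ref_t = np.array([e.time for e in ref])
        got_t = np.array([e.time for e in got])
        assert got_t.size == ref_t.size
        assert np.max(np.abs(got_t - ref_t)) <= 2.0 / clean.sample_rate
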