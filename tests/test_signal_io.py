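"""Signal conditioning: filters, resampling, normalization, clocks, GPS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import noise_free_profile
from runkin import gait_events as ge
from runkin import signal_io as sio
from runkin import synthetic_data as sd


def sine_series(freq: float, rate: float = 200.0, duration: float = 10.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    return sio.TimeSeries(t, np.sin(2 * np.pi * freq * t)[:, None], rate, ("x",))


class TestButterworth:
    def test_constant_series_unchanged(self):
        t = np.arange(0, 5, 0.005)
        ts = sio.TimeSeries(t, np.full_like(t, 3.7)[:, None], 200.0, ("x",))
        out = sio.butterworth_zero_lag(ts, 4, 35.0)
        assert np.allclose(out.values, 3.7, atol=1e-9)

    def test_passband_and_stopband_amplitudes(self):
        low = sio.butterworth_zero_lag(sine_series(2.0), 4, 20.0)
        assert np.max(np.abs(low.values)) > 0.99
        high = sio.butterworth_zero_lag(sine_series(45.0), 4, 20.0)
        assert np.max(np.abs(high.values[500:-500])) < 0.10

    def test_impulse_response_is_symmetric(self):
        t = np.arange(0, 2, 0.005)
        x = np.zeros_like(t)
        x[len(x) // 2] = 1.0
        out = sio.butterworth_zero_lag(
            sio.TimeSeries(t, x[:, None], 200.0, ("x",)), 4, 20.0)
        y = out.values[:, 0]
        c = len(y) // 2
        assert np.allclose(y[c - 50:c], y[c + 50:c:-1], atol=1e-9)

    def test_zero_phase_no_lag(self):
        ts = sine_series(5.0)
        out = sio.butterworth_zero_lag(ts, 4, 35.0)
        xc = np.correlate(out.values[:, 0], ts.values[:, 0], mode="full")
        assert abs(int(np.argmax(xc)) - (ts.n_samples - 1)) == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sio.butterworth_zero_lag(sine_series(2.0), 4, 120.0)


class TestDownsample:
    def test_length_arithmetic_200_to_100(self):
        out = sio.downsample(sine_series(2.0, duration=10.0), 100.0)
        assert abs(out.n_samples - 1000) <= 1
        assert out.sample_rate == 100.0

    def test_constant_preserved(self):
        t = np.arange(0, 5, 0.005)
        ts = sio.TimeSeries(t, np.full_like(t, 1.5)[:, None], 200.0, ("x",))
        assert np.allclose(sio.downsample(ts, 100.0).values, 1.5, atol=1e-9)

    def test_passband_tone_amplitude_preserved(self):
        out = sio.downsample(sine_series(10.0), 100.0)
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(out.values ** 2))
        assert amplitude > 0.99

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            sio.downsample(sine_series(2.0), 150.0)


class TestForceNormalization:
    def test_bodyweight_definition(self):
        t = np.arange(0, 1, 0.01)
        f = sio.ForceSeries(t, np.full_like(t, 686.7)[:, None], 100.0,
                            ("force",), unit="N")
        out = sio.normalize_bw(f, 70.0)
        assert np.allclose(out.force, 686.7 / (70.0 * 9.81))
        assert np.allclose(sio.normalize_bw(
            sio.ForceSeries(t, np.zeros_like(t)[:, None], 100.0, ("force",)),
            70.0).force, 0.0)

    def test_round_trip_identity(self):
        t = np.arange(0, 1, 0.01)
        f = sio.ForceSeries(t, (600 * np.random.default_rng(0).random(len(t)))[:, None],
                            100.0, ("force",), unit="N")
        bw = sio.normalize_bw(f, 70.0)
        back = sio.normalize_bw(sio.denormalize_bw(bw), 70.0)
        assert np.allclose(back.force, bw.force, atol=1e-12)

    def test_invalid_mass(self):
        t = np.arange(0, 1, 0.01)
        f = sio.ForceSeries(t, np.zeros_like(t)[:, None], 100.0, ("force",))
        with pytest.raises(ValueError):
            sio.normalize_bw(f, 0.0)

    def test_zero_subthreshold_example(self):
        t = np.arange(4) * 0.01
        f = sio.ForceSeries(t, np.array([0.01, 0.04, 0.05, 0.30])[:, None],
                            100.0, ("force",), unit="BW")
        out = sio.zero_subthreshold(f)
        assert np.array_equal(out.force, [0.0, 0.0, 0.05, 0.30])

    @given(st.lists(st.floats(0, 3), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_zero_subthreshold_idempotent(self, values):
        t = np.arange(len(values)) * 0.01
        f = sio.ForceSeries(t, np.array(values)[:, None], 100.0, ("force",),
                            unit="BW")
        once = sio.zero_subthreshold(f)
        twice = sio.zero_subthreshold(once)
        assert np.array_equal(once.force, twice.force)
        assert np.max(twice.force) == (np.max(f.force)
                                       if np.max(f.force) >= 0.05 else 0.0)


class TestBaselineCorrection:
    def test_zero_baseline_unchanged(self, session30_quiet):
        f = sio.normalize_bw(session30_quiet.left_force, session30_quiet.mass)
        out = sio.correct_baseline(f)
        assert np.allclose(out.force, f.force, atol=1e-12)

    def test_constant_offset_removed(self, session30_quiet):
        f = sio.normalize_bw(session30_quiet.left_force, session30_quiet.mass)
        shifted = f.copy()
        shifted.values = shifted.values + 0.04
        out = sio.correct_baseline(shifted)
        swing = f.force == 0.0
        assert np.max(np.abs(out.force[swing])) < 1e-9

    def test_drift_fixture_swing_mean(self, session30_quiet):
        drifted = sd.inject_baseline_drift(session30_quiet.left_force, 30.0,
                                           onset=5.0)
        out = sio.correct_baseline(sio.normalize_bw(drifted, session30_quiet.mass))
        ref = sio.normalize_bw(session30_quiet.left_force, session30_quiet.mass)
        swing = (ref.force == 0.0) & (ref.timestamps > 7.0)
        assert np.mean(out.force[swing]) < 0.01


class TestClockCorrection:
    def make_events(self, n=40, stride=0.7, seed=0):
        rng = np.random.default_rng(seed)
        return np.cumsum(stride + 0.01 * rng.standard_normal(n)) + 1.0

    def test_identity(self):
        ev = self.make_events()
        cm = sio.correct_clock_drift(ev, ev)
        assert abs(cm.offset) < 1e-9 and abs(cm.drift) < 1e-12
        assert cm.residual < 1e-9

    def test_exact_affine_offset(self):
        ev = self.make_events()
        cm = sio.correct_clock_drift(ev, ev + 0.5)
        assert np.isclose(cm.offset, 0.5, atol=1e-9)
        assert abs(cm.drift) < 1e-12

    def test_insufficient_events(self):
        with pytest.raises(sio.InsufficientDataError):
            sio.correct_clock_drift(np.arange(5.0), np.arange(5.0))

    def test_no_match_failure(self):
        a = np.arange(20.0)
        with pytest.raises(sio.SyncFailureError):
            # all pairwise residuals after coarse alignment stay huge
            sio.correct_clock_drift(a, np.concatenate([a[:10] * 7, a[10:] * 13]))

    def test_recovers_injected_drift(self):
        profile = noise_free_profile()
        bundle = sd.simulate_session(profile, sd.steady_course(60.0, 3.0), seed=3)
        drifted = sd.inject_clock_drift(bundle, 0.3, 5e-5)
        cm = sio.correct_clock_drift(
            drifted.truth["time_imu_s"].to_numpy(),
            drifted.truth["time_s"].to_numpy())
        inv = cm.inverse()
        assert abs(inv.offset - 0.3) < 1e-6
        assert abs(inv.drift - 5e-5) < 1e-9


class TestGPS:
    def make_trace(self, speeds):
        n = len(speeds)
        return pd.DataFrame({"time_s": np.arange(n, dtype=float),
                             "speed_mps": np.asarray(speeds, dtype=float),
                             "elevation_m": np.zeros(n)})

    def test_smooth_constant_trace_identity(self):
        trace = self.make_trace([3.0] * 30)
        out = sio.smooth_gps(trace)
        assert np.allclose(out["speed_mps"], 3.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            sio.smooth_gps(self.make_trace([]))

    def test_sync_aligns_first_speed_rise(self, session30):
        gps = session30.gps.copy()
        gps["time_s"] = gps["time_s"] + 17.0  # misaligned watch clock
        bundle = sio.SessionBundle(**{**vars(session30), "gps": gps})
        out = sio.sync_gps(bundle, first_footfall_time=0.25)
        assert np.isclose(out.gps["time_s"].iloc[0], 0.25)

    @pytest.mark.parametrize("v,expected", [
        (3.10, 3.00), (3.13, 3.25), (2.00, None), (2.125, 2.25),
        (5.375, 5.25), (5.38, None), (2.12, None), (4.0, 4.0)])
    def test_bin_velocity_examples(self, v, expected):
        assert sio.bin_velocity(v) == expected

    @pytest.mark.parametrize("member", sio.VELOCITY_BINS.tolist())
    def test_bin_members_are_fixed_points(self, member):
        assert sio.bin_velocity(member) == member

    @pytest.mark.parametrize("g,expected", [
        (6.0, "incline"), (-7.0, "decline"), (5.0, "level"), (-5.0, "level"),
        (0.0, "level"), (5.01, "incline")])
    def test_classify_grade(self, g, expected):
        assert sio.classify_grade(g) == expected


class TestSessionIO:
    def test_csv_round_trip(self, session30, tmp_path):
        path = sio.save_session(session30, tmp_path / "sess")
        back = sio.load_session(path)
        assert back.subject_id == session30.subject_id
        assert np.allclose(back.left_imu.values, session30.left_imu.values)
        assert np.allclose(back.left_force.values, session30.left_force.values)
        assert len(back.truth) == len(session30.truth)

    def test_h5_round_trip(self, session30, tmp_path):
        path = sio.save_session(session30, tmp_path / "sess.h5")
        back = sio.load_session(path)
        assert np.allclose(back.sacrum_imu.values, session30.sacrum_imu.values)
        assert back.left_force.unit == session30.left_force.unit
        assert np.allclose(back.gps["speed_mps"], session30.gps["speed_mps"])
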