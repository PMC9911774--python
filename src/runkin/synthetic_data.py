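"""Seeded simulator of outdoor running sessions with ground-truth gait events.

The generator emits the full sensor layout assumed by the detectors and the
GRF estimator: 200 Hz foot/sacrum IMU streams (gravity-aligned, vertical
channel gravity-compensated), 100 Hz per-foot insole normal force, and 1 Hz
GPS speed/elevation, for a runner following a piecewise-constant speed and
grade schedule.

Stance-phase force is modelled as the sum of two raised-cosine bells — an
early narrow impact transient (~13 % of stance) and a broad active peak
(~mid-stance, half-width ~47 % of stance) — with amplitudes calibrated so
stance averages sit near 1.2-1.4 BW and peaks near 2.2-2.6 BW over the
running-speed range, rising mildly with speed; declines accentuate and
inclines attenuate the impact transient. IMU channels are deterministic
subject-gain-scaled functions of the concurrent force plus event-locked
transients and Gaussian noise, so the summed force waveform is learnable
from the inertial channels and the heuristic event detectors' preconditions
hold by construction:

* the foot x-gyro shows a prominent local minimum 15 ms before each true IC,
* the resultant foot acceleration spikes above 50 m/s^2 at the true IC
  (carried by the x/y accelerometer channels),
* gravity-compensated vertical foot acceleration exceeds 3 g just before the
  true TO (and nowhere else inside the toe-off search window).

Ground-truth IC/TO are the 5 % BW crossing times of the continuous stance
waveform. All randomness sits behind a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import StancePhase
from .signal_io import (GRAVITY, FORCE_THRESHOLD_BW, IMU_CHANNELS, ForceSeries,
                        SessionBundle, TimeSeries, classify_grade)

IMU_RATE = 200.0
FORCE_RATE = 100.0

#: (grf gain, transients) per foot channel; transients are
#: (amplitude, center offset relative to IC [or TO], half width s, anchor).
_FOOT_TEMPLATES: dict[str, tuple[float, tuple]] = {
    "ax": (3.0, ((70.0, 0.0, 0.030, "IC"),)),
    "ay": (1.5, ((60.0, 0.0, 0.030, "IC"),)),
    "az": (6.0, ((36.0, 0.0, 0.025, "TO"),)),
    "gx": (0.8, ((-5.0, -0.015, 0.080, "IC"), (2.5, -0.300, 0.120, "IC"))),
    "gy": (0.6, ((1.2, -0.200, 0.100, "IC"),)),
    "gz": (0.4, ((0.8, -0.100, 0.060, "IC"),)),
}
#: Sacrum channels carry scaled copies of the summed (both-feet) force.
_SACRUM_GAINS = {"ax": 2.5, "ay": 1.2, "az": 8.0, "gx": 0.5, "gy": 0.4, "gz": 0.3}

#: Default per-channel noise SD: 0.8 m/s^2 on accelerometers, 0.08 rad/s on gyros.
_DEFAULT_NOISE = {"a": 0.8, "g": 0.08}


@dataclass
class StanceShapeParams:
    """Two-bell stance waveform: impact + active raised cosines (BW)."""

    impact_amplitude: float = 1.0
    impact_center_frac: float = 0.13
    impact_width_frac: float = 0.13
    active_amplitude: float = 2.35
    active_center_frac: float = 0.50
    active_width_frac: float = 0.47

    def __post_init__(self) -> None:
        if self.impact_amplitude < 0 or self.active_amplitude < 0:
            raise ValueError("bell amplitudes must be non-negative")
        for c, w in ((self.impact_center_frac, self.impact_width_frac),
                     (self.active_center_frac, self.active_width_frac)):
            if not (0.0 <= c - w + 1e-12 and c + w <= 1.0 + 1e-12):
                raise ValueError("bell support must lie within the stance")


@dataclass
class SubjectProfile:
    """Per-participant anthropometrics, gait timing and sensor response."""

    subject_id: str
    mass: float = 70.0                     # kg
    preferred_speed: float = 3.0           # m/s
    contact_time_intercept: float = 0.28   # s at 3.0 m/s
    contact_time_slope: float = 0.02       # s per m/s decrease with speed
    imu_gain_vector: dict[str, float] = field(default_factory=dict)
    noise_sd_vector: dict[str, float] = field(default_factory=dict)
    shape: StanceShapeParams = field(default_factory=StanceShapeParams)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    def contact_time(self, speed: float) -> float:
        """Linear contact-time model; decreases with running speed."""
        tc = self.contact_time_intercept - self.contact_time_slope * (speed - 3.0)
        if not 0.100 < tc < 0.500:
            raise ValueError(f"contact time {tc:.3f} s outside (0.100, 0.500)")
        return tc

    def gain(self, location: str, channel: str) -> float:
        return self.imu_gain_vector.get(f"{location}.{channel}", 1.0)

    def noise_sd(self, location: str, channel: str) -> float:
        default = _DEFAULT_NOISE[channel[0]]
        return self.noise_sd_vector.get(f"{location}.{channel}", default)


@dataclass
class CourseProfile:
    """Piecewise-constant speed/grade schedule; zero-speed segments are stops."""

    segments: tuple[tuple[float, float, float], ...]  # (duration s, speed m/s, grade deg)
    grade_noise_sd: float = 4.0  # deg, matches field noise on flat sections

    def __post_init__(self) -> None:
        for dur, speed, grade in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if speed < 0:
                raise ValueError("speeds must be >= 0")
            if abs(grade) > 8.0:
                raise ValueError("grades must lie within +-8 degrees")

    @property
    def duration(self) -> float:
        return float(sum(d for d, _, _ in self.segments))

    def boundaries(self) -> list[tuple[float, float, float, float]]:
        """(start, end, speed, grade) per segment."""
        out, t = [], 0.0
        for dur, speed, grade in self.segments:
            out.append((t, t + dur, speed, grade))
            t += dur
        return out


def steady_course(duration: float, speed: float, grade: float = 0.0,
                  grade_noise_sd: float = 4.0) -> CourseProfile:
    return CourseProfile(segments=((duration, speed, grade),),
                         grade_noise_sd=grade_noise_sd)


def default_cohort(n_subjects: int, seed: int,
                   gain_spread: float = 0.03) -> list[SubjectProfile]:
    """Deterministic cohort with subject-specific mass, timing and IMU gains."""
    rng = np.random.default_rng(seed)
    cohort = []
    for k in range(n_subjects):
        gains = {}
        for loc in ("left", "right", "sacrum"):
            for ch in IMU_CHANNELS:
                gains[f"{loc}.{ch}"] = float(1.0 + gain_spread * rng.standard_normal())
        cohort.append(SubjectProfile(
            subject_id=f"S{k:02d}",
            mass=float(rng.uniform(55.0, 85.0)),
            preferred_speed=float(rng.uniform(2.8, 3.8)),
            contact_time_intercept=float(0.28 + rng.normal(0.0, 0.008)),
            contact_time_slope=float(0.02 + rng.normal(0.0, 0.002)),
            imu_gain_vector=gains))
    return cohort


# ---------------------------------------------------------------------------
# stance waveform
# ---------------------------------------------------------------------------

def _bell(x: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine bell: 0.5*(1+cos(pi*(x-c)/w)) on |x-c|<=w, else 0."""
    d = (np.asarray(x, dtype=float) - center) / half_width
    out = np.zeros_like(d)
    inside = np.abs(d) <= 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside]))
    return out


def _speed_scale(speed: float) -> float:
    return 1.0 + 0.05 * (speed - 3.0)


_IMPACT_GRADE_FACTOR = {"level": 1.0, "decline": 1.5, "incline": 0.6}


def stance_waveform(u: np.ndarray, speed: float, grade_class: str,
                    shape: StanceShapeParams) -> np.ndarray:
    """Stance force (BW) at normalized stance time u in [0, 1]."""
    scale = _speed_scale(speed)
    a_imp = shape.impact_amplitude * scale * _IMPACT_GRADE_FACTOR[grade_class]
    a_act = shape.active_amplitude * scale
    return (a_imp * _bell(u, shape.impact_center_frac, shape.impact_width_frac)
            + a_act * _bell(u, shape.active_center_frac, shape.active_width_frac))


def simulate_grf_stance(speed: float, grade_class: str, contact_time: float,
                        shape: StanceShapeParams | None = None,
                        sample_rate: float = FORCE_RATE) -> StancePhase:
    """One stance-phase force waveform sampled at ``sample_rate``."""
    if speed <= 0 or contact_time <= 0:
        raise ValueError("speed and contact_time must be positive")
    if not 0.100 < contact_time < 0.500:
        raise ValueError("contact_time must lie in (0.100, 0.500) s")
    if sample_rate < 100:
        raise ValueError("sample_rate must be >= 100 Hz")
    shape = shape or StanceShapeParams()
    n = int(np.floor(contact_time * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    force = stance_waveform(t / contact_time, speed, grade_class, shape)
    return StancePhase(times=t, force=force)


def stride_time(speed: float) -> float:
    """Stride (same-foot IC to IC) duration; cadence rises mildly with speed."""
    return 60.0 / (72.0 + 3.0 * speed)


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

@dataclass
class _Contact:
    side: str
    t0: float          # nominal stance start, force clock
    tc: float          # nominal contact duration
    speed: float
    grade: float
    ic: float = 0.0    # truth 5 % BW crossing times
    to: float = 0.0

    @property
    def grade_class(self) -> str:
        return classify_grade(self.grade)


def _truth_crossings(contact: _Contact, shape: StanceShapeParams,
                     threshold: float = FORCE_THRESHOLD_BW) -> tuple[float, float]:
    """First/last crossings of the 5 % BW threshold on a fine grid."""
    u = np.linspace(0.0, 1.0, 2001)
    w = stance_waveform(u, contact.speed, contact.grade_class, shape)
    above = np.flatnonzero(w >= threshold)
    if above.size == 0:
        raise ValueError("stance waveform never reaches the contact threshold")

    def interp(i_lo: int, i_hi: int) -> float:
        u0, u1, w0, w1 = u[i_lo], u[i_hi], w[i_lo], w[i_hi]
        if w1 == w0:
            return u0
        return u0 + (threshold - w0) * (u1 - u0) / (w1 - w0)

    first, last = above[0], above[-1]
    u_ic = interp(first - 1, first) if first > 0 else 0.0
    u_to = interp(last + 1, last) if last < u.size - 1 else 1.0
    return contact.t0 + u_ic * contact.tc, contact.t0 + u_to * contact.tc


def _schedule_contacts(profile: SubjectProfile, course: CourseProfile) -> list[_Contact]:
    contacts: list[_Contact] = []
    for start, end, speed, grade in course.boundaries():
        if speed <= 0:
            continue
        tc = profile.contact_time(speed)
        stride = stride_time(speed)
        for side, t in (("left", start + 0.25), ("right", start + 0.25 + stride / 2)):
            while t + tc <= end - 0.02:
                contacts.append(_Contact(side=side, t0=t, tc=tc,
                                         speed=speed, grade=grade))
                t += stride
    contacts.sort(key=lambda c: c.t0)
    return contacts


def _accumulate_force(t: np.ndarray, contacts: list[_Contact], side: str,
                      shape: StanceShapeParams) -> np.ndarray:
    force = np.zeros_like(t)
    for c in contacts:
        if c.side != side:
            continue
        i0 = np.searchsorted(t, c.t0)
        i1 = np.searchsorted(t, c.t0 + c.tc, side="right")
        seg = t[i0:i1]
        force[i0:i1] += stance_waveform((seg - c.t0) / c.tc, c.speed,
                                        c.grade_class, shape)
    return force


def _add_transient(values: np.ndarray, t: np.ndarray, center: float,
                   half_width: float, amplitude: float) -> None:
    i0 = np.searchsorted(t, center - half_width)
    i1 = np.searchsorted(t, center + half_width, side="right")
    if i1 > i0:
        values[i0:i1] += amplitude * _bell(t[i0:i1], center, half_width)


def _synthesize_foot_imu(t: np.ndarray, grf_bw: np.ndarray,
                         contacts: list[_Contact], side: str,
                         profile: SubjectProfile,
                         rng: np.random.Generator) -> TimeSeries:
    cols = []
    for ch in IMU_CHANNELS:
        grf_gain, transients = _FOOT_TEMPLATES[ch]
        sig = grf_gain * grf_bw.copy()
        for amp, rel, width, anchor in transients:
            for c in contacts:
                if c.side != side:
                    continue
                center = (c.ic if anchor == "IC" else c.to) + rel
                _add_transient(sig, t, center, width, amp)
        sig *= profile.gain(side, ch)
        sd = profile.noise_sd(side, ch)
        if sd > 0:
            sig = sig + rng.normal(0.0, sd, size=sig.shape)
        cols.append(sig)
    return TimeSeries(t.copy(), np.stack(cols, axis=1), IMU_RATE, IMU_CHANNELS)


def _synthesize_sacrum_imu(t: np.ndarray, total_grf_bw: np.ndarray,
                           profile: SubjectProfile,
                           rng: np.random.Generator) -> TimeSeries:
    cols = []
    for ch in IMU_CHANNELS:
        sig = _SACRUM_GAINS[ch] * total_grf_bw * profile.gain("sacrum", ch)
        sd = profile.noise_sd("sacrum", ch)
        if sd > 0:
            sig = sig + rng.normal(0.0, sd, size=sig.shape)
        cols.append(sig)
    return TimeSeries(t.copy(), np.stack(cols, axis=1), IMU_RATE, IMU_CHANNELS)


def _synthesize_gps(course: CourseProfile, rng: np.random.Generator) -> pd.DataFrame:
    times = np.arange(0.0, course.duration + 1e-9, 1.0)
    speed = np.zeros_like(times)
    grade = np.zeros_like(times)
    for start, end, v, g in course.boundaries():
        mask = (times >= start) & (times < end)
        speed[mask] = v
        grade[mask] = g
    if times.size and course.duration > 0:
        speed[-1], grade[-1] = speed[-2], grade[-2]
    noisy_grade = grade + rng.normal(0.0, course.grade_noise_sd, size=grade.shape)
    delev = speed * np.tan(np.radians(noisy_grade))  # per-second elevation step
    elevation = 100.0 + np.concatenate(([0.0], np.cumsum(delev[:-1])))
    return pd.DataFrame({"time_s": times, "speed_mps": speed,
                         "elevation_m": elevation})


def simulate_session(profile: SubjectProfile, course: CourseProfile,
                     seed: int) -> SessionBundle:
    """Generate one fully annotated running session.

    Returns raw (unconditioned) streams: IMUs at 200 Hz, insole forces in
    newtons at 100 Hz, GPS at 1 Hz, and a truth table of IC/TO events per
    foot on both the force clock (``time_s``) and the IMU clock
    (``time_imu_s``; identical until :func:`inject_clock_drift`).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if course.duration < 10:
        raise ValueError("course duration must be at least 10 s")
    rng = np.random.default_rng(seed)

    contacts = _schedule_contacts(profile, course)
    for c in contacts:
        c.ic, c.to = _truth_crossings(c, profile.shape)

    t_force = np.arange(0.0, course.duration, 1.0 / FORCE_RATE)
    t_imu = np.arange(0.0, course.duration, 1.0 / IMU_RATE)
    bw = profile.mass * GRAVITY

    forces, grf_imu = {}, {}
    for side in ("left", "right"):
        f_bw = _accumulate_force(t_force, contacts, side, profile.shape)
        forces[side] = ForceSeries(t_force.copy(), (f_bw * bw)[:, None],
                                   FORCE_RATE, (f"force_{side}",),
                                   unit="N", body_weight=bw)
        grf_imu[side] = _accumulate_force(t_imu, contacts, side, profile.shape)

    left_imu = _synthesize_foot_imu(t_imu, grf_imu["left"], contacts, "left",
                                    profile, rng)
    right_imu = _synthesize_foot_imu(t_imu, grf_imu["right"], contacts, "right",
                                     profile, rng)
    sacrum = _synthesize_sacrum_imu(t_imu, grf_imu["left"] + grf_imu["right"],
                                    profile, rng)
    gps = _synthesize_gps(course, rng)

    rows = []
    for c in contacts:
        for kind, time in (("IC", c.ic), ("TO", c.to)):
            rows.append({"event": kind, "side": c.side, "time_s": time,
                         "time_imu_s": time, "speed_mps": c.speed,
                         "grade_deg": c.grade})
    truth_cols = ("event", "side", "time_s", "time_imu_s", "speed_mps",
                  "grade_deg")
    truth = pd.DataFrame(rows, columns=truth_cols).sort_values(
        "time_s", ignore_index=True)

    return SessionBundle(subject_id=profile.subject_id, mass=profile.mass,
                         left_imu=left_imu, right_imu=right_imu,
                         sacrum_imu=sacrum, left_force=forces["left"],
                         right_force=forces["right"], gps=gps, truth=truth,
                         meta={"seed": seed})


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_clock_drift(bundle: SessionBundle, offset: float,
                       drift: float) -> SessionBundle:
    """Relabel IMU timestamps t -> offset + (1+drift)*t; force clock untouched.

    The truth table's ``time_imu_s`` column follows the IMU relabelling so
    both clocks remain available for recovery checks.
    """
    if abs(drift) >= 0.01:
        raise ValueError("|drift| must be below 0.01")

    def remap(ts: TimeSeries) -> TimeSeries:
        new = ts.copy()
        new.timestamps = offset + (1.0 + drift) * ts.timestamps
        return new

    truth = bundle.truth
    if truth is not None:
        truth = truth.copy()
        truth["time_imu_s"] = offset + (1.0 + drift) * truth["time_imu_s"]
    return replace(bundle, left_imu=remap(bundle.left_imu),
                   right_imu=remap(bundle.right_imu),
                   sacrum_imu=remap(bundle.sacrum_imu), truth=truth)


def inject_baseline_drift(force: ForceSeries, magnitude: float,
                          onset: float, period_s: float = 20.0) -> ForceSeries:
    """Add a slow positive baseline after ``onset`` (newtons).

    The offset is a sinusoid of amplitude magnitude/3 around ``magnitude``
    (period ``period_s``), emulating an insole shifting inside the shoe, so
    swing-phase force stays within [2/3, 4/3] * magnitude after onset.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return force.copy()
    new = force.copy()
    t = new.timestamps
    after = t >= onset
    wobble = magnitude + (magnitude / 3.0) * np.sin(
        2.0 * np.pi * (t[after] - onset) / period_s)
    new.values[after, :] += wobble[:, None]
    return new
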