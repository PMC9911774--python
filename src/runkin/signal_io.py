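"""Session containers, signal conditioning and multi-sensor synchronization.

This module holds the in-memory representation of a recorded running session
(foot/sacrum IMU streams at 200 Hz, per-foot insole normal force at 100 Hz,
1 Hz GPS speed and elevation) together with every conditioning step applied
before event detection and model training: zero-lag Butterworth filtering,
decimation to the force sampling rate, body-weight normalization, 5 % BW
zeroing, swing-phase baseline correction, iterative clock-drift correction
between the IMU and insole clocks, GPS smoothing/synchronization, and the
velocity-bin / grade-class annotation used to stratify footfalls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

GRAVITY = 9.81
#: Force below this fraction of body weight is treated as no contact.
FORCE_THRESHOLD_BW = 0.05
#: Velocity bins, m/s (nearest-0.25 grid used for stratified reporting).
VELOCITY_BINS = np.round(np.arange(2.25, 5.25 + 1e-9, 0.25), 2)
#: Grades steeper than +5 deg are incline, below -5 deg decline.
GRADE_LIMIT_DEG = 5.0

IMU_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")


class InsufficientDataError(ValueError):
    """Raised when an operation receives fewer samples/events than it needs."""


class SyncFailureError(RuntimeError):
    """Raised when clock synchronization cannot match any events."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """Uniformly sampled multi-channel series.

    ``values`` is (n_samples, n_channels); ``timestamps`` are seconds,
    strictly increasing and nominally uniform at ``sample_rate``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    sample_rate: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values and timestamps disagree in length")
        if self.timestamps.size > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names does not match value columns")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]

    def copy(self) -> "TimeSeries":
        return replace(self, timestamps=self.timestamps.copy(),
                       values=self.values.copy())


@dataclass
class ForceSeries(TimeSeries):
    """Single-channel normal force, in newtons or body weights (BW)."""

    unit: str = "N"
    body_weight: float = float("nan")  # newtons

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.unit not in ("N", "BW"):
            raise ValueError(f"unknown force unit {self.unit!r}")

    @property
    def force(self) -> np.ndarray:
        return self.values[:, 0]


@dataclass
class ClockMap:
    """Affine map from the IMU clock to the force clock: t -> offset + (1+drift)*t."""

    offset: float
    drift: float
    iterations_used: int = 0
    residual: float = 0.0

    def apply(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.offset + (1.0 + self.drift) * np.asarray(t, dtype=float)

    def inverse(self) -> "ClockMap":
        """Map in the opposite direction (force clock to IMU clock)."""
        scale = 1.0 / (1.0 + self.drift)
        return ClockMap(offset=-self.offset * scale, drift=scale - 1.0,
                        iterations_used=self.iterations_used,
                        residual=self.residual)

    def compose(self, inner: "ClockMap") -> "ClockMap":
        # self(inner(t)) = off_s + (1+d_s)(off_i + (1+d_i) t)
        scale = (1.0 + self.drift) * (1.0 + inner.drift)
        off = self.offset + (1.0 + self.drift) * inner.offset
        return ClockMap(offset=off, drift=scale - 1.0,
                        iterations_used=self.iterations_used,
                        residual=self.residual)


@dataclass
class SessionBundle:
    """One synchronized running session for one participant.

    IMU streams are gravity-aligned (vertical channel ``az`` is gravity
    compensated); forces are insole normal forces in newtons until
    :func:`normalize_bw` is applied. ``truth`` optionally carries
    ground-truth gait events with columns ``event, side, time_s`` (force
    clock) and ``time_imu_s`` (IMU clock).
    """

    subject_id: str
    mass: float  # kg
    left_imu: TimeSeries
    right_imu: TimeSeries
    sacrum_imu: TimeSeries
    left_force: ForceSeries
    right_force: ForceSeries
    gps: pd.DataFrame  # columns: time_s, speed_mps, elevation_m
    truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def body_weight(self) -> float:
        return self.mass * GRAVITY

    def imu_streams(self) -> dict[str, TimeSeries]:
        return {"left": self.left_imu, "right": self.right_imu,
                "sacrum": self.sacrum_imu}


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------

def butterworth_zero_lag(series: TimeSeries, order: int, cutoff: float) -> TimeSeries:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    ``order`` is the per-direction design order; forward-backward
    application doubles the effective order but leaves phase at zero.
    """
    nyq = series.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    if series.n_samples <= 3 * order:
        raise InsufficientDataError("series too short for requested filter order")
    sos = sps.butter(order, cutoff, btype="low", fs=series.sample_rate, output="sos")
    out = sps.sosfiltfilt(sos, series.values, axis=0)
    new = series.copy()
    new.values = out
    return new


def downsample(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Decimate to ``target_rate`` (integer factor) with an anti-alias guard.

    A zero-lag low-pass at 0.45 * target Nyquist-rate is applied before
    keeping every ``factor``-th sample; timestamps of kept samples are
    preserved.
    """
    ratio = series.sample_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"sample rate {series.sample_rate} is not an integer "
                         f"multiple of target {target_rate}")
    if factor == 1:
        return series.copy()
    guarded = butterworth_zero_lag(series, order=4, cutoff=0.45 * target_rate)
    new = replace(series,
                  timestamps=guarded.timestamps[::factor].copy(),
                  values=guarded.values[::factor].copy(),
                  sample_rate=target_rate)
    return new


# ---------------------------------------------------------------------------
# force conditioning
# ---------------------------------------------------------------------------

def normalize_bw(force: ForceSeries, mass: float) -> ForceSeries:
    """Convert a force series from newtons to body weights (mass * g)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if force.unit == "BW":
        return force.copy()
    bw = mass * GRAVITY
    new = force.copy()
    new.values = force.values / bw
    new.unit = "BW"
    new.body_weight = bw
    return new


def denormalize_bw(force: ForceSeries) -> ForceSeries:
    if force.unit == "N":
        return force.copy()
    new = force.copy()
    new.values = force.values * force.body_weight
    new.unit = "N"
    return new


def zero_subthreshold(force: ForceSeries, threshold: float = FORCE_THRESHOLD_BW) -> ForceSeries:
    """Set samples below 5 % BW to exactly 0 BW (idempotent)."""
    if force.unit != "BW":
        raise ValueError("zero_subthreshold expects BW-normalized force")
    new = force.copy()
    new.values = np.where(new.values < threshold, 0.0, new.values)
    return new


def correct_baseline(force: ForceSeries,
                     min_swing_duration: float = 0.05,
                     swing_fraction: float = 0.25,
                     peak_window_s: float = 1.0) -> ForceSeries:
    """Re-zero a drifting swing-phase baseline.

    Swing segments are runs of at least ``min_swing_duration`` where force is
    below ``swing_fraction`` of the local cycle peak (a ~1 s moving maximum).
    The baseline is the per-segment swing median, interpolated across stance,
    subtracted everywhere and the result clipped at 0.
    """
    if force.unit != "BW":
        raise ValueError("correct_baseline expects BW-normalized force")
    from scipy.ndimage import maximum_filter1d

    f = force.force
    n = f.shape[0]
    win = max(3, int(round(peak_window_s * force.sample_rate)))
    local_peak = maximum_filter1d(f, size=win, mode="nearest")
    swing = f < swing_fraction * np.maximum(local_peak, FORCE_THRESHOLD_BW)
    min_len = max(1, int(round(min_swing_duration * force.sample_rate)))

    knots_t, knots_v = [], []
    for start, stop in _runs(swing):
        if stop - start >= min_len:
            knots_t.append(0.5 * (force.timestamps[start] + force.timestamps[stop - 1]))
            knots_v.append(float(np.median(f[start:stop])))
    new = force.copy()
    if not knots_t:
        return new
    baseline = np.interp(force.timestamps, knots_t, knots_v)
    new.values = np.clip(f - baseline, 0.0, None)[:, None]
    return new


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# clock synchronization
# ---------------------------------------------------------------------------

def correct_clock_drift(imu_events: np.ndarray, force_events: np.ndarray,
                        max_iter: int = 10,
                        match_window: float = 0.25,
                        tol: float = 0.005) -> ClockMap:
    """Estimate the affine IMU->force clock map from two gait-event lists.

    The two clocks are first coarsely aligned by the median time difference
    (gait events repeat every ~0.35 s, so an uninformed nearest-neighbour
    match could pair across steps for large offsets). Then, iteratively:
    greedy nearest-time one-to-one matching within ``match_window``, a
    least-squares fit of force_time = offset + (1+drift) * imu_time over the
    matches, and a remap — until the median absolute residual drops below
    half a force sample period (0.005 s).
    """
    imu_events = np.sort(np.asarray(imu_events, dtype=float))
    force_events = np.sort(np.asarray(force_events, dtype=float))
    if imu_events.size < 10 or force_events.size < 10:
        raise InsufficientDataError("need at least 10 events in each list")

    cmap = ClockMap(offset=float(np.median(force_events) - np.median(imu_events)),
                    drift=0.0)
    residual = np.inf
    for it in range(1, max_iter + 1):
        mapped = cmap.apply(imu_events)
        pairs = _greedy_match(mapped, force_events, match_window)
        if not pairs:
            raise SyncFailureError("no event matches within the matching window")
        i_idx = np.array([p[0] for p in pairs])
        f_idx = np.array([p[1] for p in pairs])
        x, y = imu_events[i_idx], force_events[f_idx]
        # Fit on the original imu clock so the map stays in one piece.
        A = np.stack([np.ones_like(x), x], axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        cmap = ClockMap(offset=float(coef[0]), drift=float(coef[1] - 1.0),
                        iterations_used=it)
        residual = float(np.median(np.abs(cmap.apply(x) - y)))
        cmap.residual = residual
        if residual < tol:
            break
    return cmap


def _greedy_match(a: np.ndarray, b: np.ndarray, window: float) -> list[tuple[int, int]]:
    """Greedy nearest-time one-to-one matching of sorted time lists."""
    cand: list[tuple[float, int, int]] = []
    j_near = np.searchsorted(b, a)
    for i, t in enumerate(a):
        for j in (j_near[i] - 1, j_near[i]):
            if 0 <= j < b.size:
                d = abs(t - b[j])
                if d <= window:
                    cand.append((d, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, i, j in cand:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    pairs.sort()
    return pairs


def apply_clock_map(bundle: SessionBundle, cmap: ClockMap) -> SessionBundle:
    """Remap every IMU stream's timestamps onto the force clock."""
    def remap(ts: TimeSeries) -> TimeSeries:
        new = ts.copy()
        new.timestamps = np.asarray(cmap.apply(ts.timestamps))
        return new

    return replace(bundle,
                   left_imu=remap(bundle.left_imu),
                   right_imu=remap(bundle.right_imu),
                   sacrum_imu=remap(bundle.sacrum_imu))


# ---------------------------------------------------------------------------
# GPS handling and stratification
# ---------------------------------------------------------------------------

def smooth_gps(trace: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Centered zero-lag moving average (default 10 samples), reflected edges."""
    if len(trace) == 0:
        raise ValueError("empty GPS trace")
    out = trace.copy()
    for col in ("speed_mps", "elevation_m"):
        if col in out:
            x = out[col].to_numpy(dtype=float)
            pad_l, pad_r = window // 2, window - window // 2 - 1
            xp = np.pad(x, (pad_l, pad_r), mode="reflect") if x.size > 1 else x
            kernel = np.ones(window) / window
            out[col] = np.convolve(xp, kernel, mode="valid") if x.size > 1 else x
    return out


def gps_grade(trace: pd.DataFrame) -> np.ndarray:
    """Per-sample grade in degrees from smoothed elevation and speed.

    grade = arctan(d elevation / d distance), distance from speed integration;
    zero where the runner is (nearly) stationary.
    """
    speed = trace["speed_mps"].to_numpy(dtype=float)
    elev = trace["elevation_m"].to_numpy(dtype=float)
    t = trace["time_s"].to_numpy(dtype=float)
    dt = np.gradient(t)
    ddist = speed * dt
    delev = np.gradient(elev)
    grade = np.zeros_like(speed)
    moving = ddist > 0.5  # m per sample; below this grade is undefined
    grade[moving] = np.degrees(np.arctan2(delev[moving], ddist[moving]))
    return grade


def sync_gps(bundle: SessionBundle, first_footfall_time: float,
             sustained_speed: float = 1.0, sustained_duration: float = 3.0
             ) -> SessionBundle:
    """Shift GPS time so the first sustained speed rise meets the first footfall.

    The first GPS sample opening a run of speed > ``sustained_speed`` lasting
    at least ``sustained_duration`` is aligned to ``first_footfall_time``.
    """
    gps = bundle.gps
    speed = gps["speed_mps"].to_numpy(dtype=float)
    t = gps["time_s"].to_numpy(dtype=float)
    need = max(1, int(round(sustained_duration)))
    start = None
    for s, e in _runs(speed > sustained_speed):
        if e - s >= need:
            start = s
            break
    if start is None:
        return bundle
    shifted = gps.copy()
    shifted["time_s"] = t - t[start] + first_footfall_time
    return replace(bundle, gps=shifted)


def bin_velocity(v: float) -> float | None:
    """Nearest 0.25 m/s bin in [2.25, 5.25]; midpoints round up.

    Velocities below 2.125 m/s (walking) or above 5.375 m/s return None.
    """
    if not np.isfinite(v) or v < 2.125 or v > 5.375:
        return None
    idx = int(np.floor((v - VELOCITY_BINS[0]) / 0.25 + 0.5))
    idx = min(max(idx, 0), len(VELOCITY_BINS) - 1)
    return float(VELOCITY_BINS[idx])


def classify_grade(g: float) -> str:
    """incline above +5 deg, decline below -5 deg, level in [-5, +5]."""
    if g > GRADE_LIMIT_DEG:
        return "incline"
    if g < -GRADE_LIMIT_DEG:
        return "decline"
    return "level"


def annotate_speed_grade(times: np.ndarray, gps: pd.DataFrame
                         ) -> tuple[list[float | None], list[str]]:
    """Velocity bin and grade class at each event time (nearest GPS second)."""
    gps_s = smooth_gps(gps)
    grade = gps_grade(gps_s)
    gt = gps_s["time_s"].to_numpy(dtype=float)
    speed = gps_s["speed_mps"].to_numpy(dtype=float)
    idx = np.clip(np.searchsorted(gt, np.asarray(times)), 0, len(gt) - 1)
    bins = [bin_velocity(float(speed[i])) for i in idx]
    classes = [classify_grade(float(grade[i])) for i in idx]
    return bins, classes


# ---------------------------------------------------------------------------
# whole-session preprocessing
# ---------------------------------------------------------------------------

def preprocess(bundle: SessionBundle, imu_fc: float = 35.0, force_fc: float = 20.0,
               target_rate: float = 100.0, baseline: bool = True,
               sync_clocks: bool = False) -> SessionBundle:
    """Standard conditioning pipeline applied to a raw session.

    IMU: decimate 200 -> ``target_rate`` Hz, then 4th-order zero-lag low-pass
    at ``imu_fc``. Force: BW-normalize, 4th-order zero-lag low-pass at
    ``force_fc``, optional swing-baseline correction, then 5 % BW zeroing.
    """
    def cond_imu(ts: TimeSeries) -> TimeSeries:
        return butterworth_zero_lag(downsample(ts, target_rate), 4, imu_fc)

    def cond_force(fs: ForceSeries) -> ForceSeries:
        f = normalize_bw(fs, bundle.mass)
        f = butterworth_zero_lag(f, 4, force_fc)
        if baseline:
            f = correct_baseline(f)
        return zero_subthreshold(f)

    out = replace(bundle,
                  left_imu=cond_imu(bundle.left_imu),
                  right_imu=cond_imu(bundle.right_imu),
                  sacrum_imu=cond_imu(bundle.sacrum_imu),
                  left_force=cond_force(bundle.left_force),
                  right_force=cond_force(bundle.right_force))
    if sync_clocks:
        from . import gait_events as ge
        cmap = estimate_session_clock_map(out)
        out = apply_clock_map(out, cmap)
        out.meta = dict(out.meta, clock_map=vars(cmap))
    return out


def estimate_session_clock_map(bundle: SessionBundle) -> ClockMap:
    """Fit the IMU->force clock map from detected events on both feet."""
    from . import gait_events as ge

    imu_times, force_times = [], []
    for side, imu, force in (("left", bundle.left_imu, bundle.left_force),
                             ("right", bundle.right_imu, bundle.right_force)):
        ics, _ = ge.detect_events_imu(imu, side=side)
        imu_times.extend(e.time for e in ics)
        fev = ge.detect_events_force(force, side=side)
        force_times.extend(e.time for e in fev if e.kind == "IC")
    return correct_clock_drift(np.array(imu_times), np.array(force_times))


# ---------------------------------------------------------------------------
# session serialization (HDF5 or a directory of CSVs)
# ---------------------------------------------------------------------------

_STREAMS = ("left_imu", "right_imu", "sacrum_imu", "left_force", "right_force")


def save_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session to ``*.h5`` (HDF5) or to a directory of CSV files."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _save_h5(bundle, path)
    path.mkdir(parents=True, exist_ok=True)
    for name in _STREAMS:
        ts: TimeSeries = getattr(bundle, name)
        df = pd.DataFrame(ts.values, columns=list(ts.channel_names))
        df.insert(0, "time_s", ts.timestamps)
        df.to_csv(path / f"{name}.csv", index=False)
    bundle.gps.to_csv(path / "gps.csv", index=False)
    if bundle.truth is not None:
        bundle.truth.to_csv(path / "truth.csv", index=False)
    meta = {"subject_id": bundle.subject_id, "mass": bundle.mass,
            "rates": {name: getattr(bundle, name).sample_rate for name in _STREAMS},
            "units": {"left_force": bundle.left_force.unit,
                      "right_force": bundle.right_force.unit},
            **bundle.meta}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_session(path: str | Path) -> SessionBundle:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_h5(path)
    meta = json.loads((path / "meta.json").read_text())
    streams = {}
    for name in _STREAMS:
        df = pd.read_csv(path / f"{name}.csv")
        t = df.pop("time_s").to_numpy()
        rate = meta["rates"][name]
        if "force" in name:
            streams[name] = ForceSeries(t, df.to_numpy(), rate,
                                        tuple(df.columns),
                                        unit=meta["units"][name],
                                        body_weight=meta["mass"] * GRAVITY)
        else:
            streams[name] = TimeSeries(t, df.to_numpy(), rate, tuple(df.columns))
    gps = pd.read_csv(path / "gps.csv")
    truth_path = path / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    extra = {k: v for k, v in meta.items()
             if k not in ("subject_id", "mass", "rates", "units")}
    return SessionBundle(subject_id=meta["subject_id"], mass=meta["mass"],
                         gps=gps, truth=truth, meta=extra, **streams)


def _save_h5(bundle: SessionBundle, path: Path) -> Path:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["subject_id"] = bundle.subject_id
        h5.attrs["mass"] = bundle.mass
        for name in _STREAMS:
            ts: TimeSeries = getattr(bundle, name)
            grp = h5.create_group(name)
            grp.create_dataset("time_s", data=ts.timestamps)
            grp.create_dataset("values", data=ts.values)
            grp.attrs["sample_rate"] = ts.sample_rate
            grp.attrs["channels"] = ",".join(ts.channel_names)
            if isinstance(ts, ForceSeries):
                grp.attrs["unit"] = ts.unit
        grp = h5.create_group("gps")
        for col in bundle.gps.columns:
            grp.create_dataset(col, data=bundle.gps[col].to_numpy())
        if bundle.truth is not None:
            grp = h5.create_group("truth")
            for col in bundle.truth.columns:
                data = bundle.truth[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                grp.create_dataset(col, data=data)
    return path


def _load_h5(path: Path) -> SessionBundle:
    import h5py

    streams = {}
    with h5py.File(path, "r") as h5:
        subject_id = str(h5.attrs["subject_id"])
        mass = float(h5.attrs["mass"])
        for name in _STREAMS:
            grp = h5[name]
            channels = tuple(str(grp.attrs["channels"]).split(","))
            if "force" in name:
                streams[name] = ForceSeries(grp["time_s"][:], grp["values"][:],
                                            float(grp.attrs["sample_rate"]),
                                            channels, unit=str(grp.attrs["unit"]),
                                            body_weight=mass * GRAVITY)
            else:
                streams[name] = TimeSeries(grp["time_s"][:], grp["values"][:],
                                           float(grp.attrs["sample_rate"]), channels)
        gps = pd.DataFrame({col: h5["gps"][col][:] for col in h5["gps"]})
        truth = None
        if "truth" in h5:
            cols = {}
            for col in h5["truth"]:
                data = h5["truth"][col][:]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            truth = pd.DataFrame(cols)
    return SessionBundle(subject_id=subject_id, mass=mass, gps=gps,
                         truth=truth, **streams)
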