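"""Estimation of ground-reaction-force waveforms from inertial windows.

One-second windows of 24 inertial channels (3 sensor locations x
(3 accelerations + resultant + 3 angular velocities + resultant), 100 Hz)
are mapped to the concurrent summed both-feet insole force (BW) by a
bidirectional LSTM with 19 hidden units, a per-timestep fully connected
sigmoid layer and a linear regression output, trained with Adam
(lr 0.001, batch 50, 100 epochs) on mean squared error.

Estimated waveforms are post-processed in order: 2nd-order zero-lag 15 Hz
low-pass, sub-5 %-BW zeroing, and removal of implausible "foot contacts"
shorter than 0.100 s or longer than 0.500 s (quiet standing). The estimator
is evaluated by leave-one-subject-out cross-validation: inputs are z-scored
with statistics computed exclusively from the training subjects of each
fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gait_events as ge
from ._bdlstm import BiLSTMRegressor
from .signal_io import (FORCE_THRESHOLD_BW, ForceSeries, SessionBundle,
                        TimeSeries, butterworth_zero_lag, zero_subthreshold,
                        _runs)

log = logging.getLogger(__name__)

#: Input channel order: per location, accelerations, their resultant,
#: angular velocities, their resultant.
CHANNEL_ORDER = tuple(
    f"{loc}.{ch}"
    for loc in ("left", "right", "sacrum")
    for ch in ("ax", "ay", "az", "a_res", "gx", "gy", "gz", "g_res"))

#: Estimated contacts outside this duration range are pruned, seconds.
CONTACT_DURATION_RANGE = (0.100, 0.500)


@dataclass
class WindowSpec:
    length: float = 1.0    # s
    rate: float = 100.0    # Hz
    overlap: float = 0.0   # fraction of a window shared with the next

    def __post_init__(self) -> None:
        n = self.length * self.rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("length * rate must be an integer")
        if not 0.0 <= self.overlap <= 0.9:
            raise ValueError("overlap must lie in [0, 0.9]")

    @property
    def samples(self) -> int:
        return int(round(self.length * self.rate))

    @property
    def step(self) -> int:
        return max(1, int(round(self.samples * (1.0 - self.overlap))))


@dataclass
class WindowedDataset:
    inputs: np.ndarray                  # (windows, samples, 24)
    targets: np.ndarray                 # (windows, samples), BW
    channel_order: tuple[str, ...]
    subject_ids: list[str]
    start_times: np.ndarray
    normalization_stats: dict | None = None

    @property
    def n_windows(self) -> int:
        return self.inputs.shape[0]

    def concat(self, other: "WindowedDataset") -> "WindowedDataset":
        if self.channel_order != other.channel_order:
            raise ValueError("channel orders differ")
        return WindowedDataset(
            inputs=np.concatenate([self.inputs, other.inputs]),
            targets=np.concatenate([self.targets, other.targets]),
            channel_order=self.channel_order,
            subject_ids=self.subject_ids + other.subject_ids,
            start_times=np.concatenate([self.start_times, other.start_times]))


@dataclass
class TrainingConfig:
    hidden_units: int = 19
    epochs: int = 100
    batch_size: int = 50
    learning_rate: float = 0.001
    seed: int = 0
    fc_units: int | None = None  # defaults to the window sample count

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.epochs, self.batch_size) <= 0:
            raise ValueError("hidden_units, epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ModelArtifact:
    model: BiLSTMRegressor
    normalization_stats: dict
    config: TrainingConfig
    channel_order: tuple[str, ...]
    window: WindowSpec
    training_subjects: list[str] = field(default_factory=list)
    training_loss: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def _input_matrix(bundle: SessionBundle, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Stack the 24 inertial channels at the force rate; returns (t, matrix)."""
    cols = []
    ref_t = None
    for loc, stream in bundle.imu_streams().items():
        if abs(stream.sample_rate - rate) > 1e-6:
            raise ValueError(f"{loc} IMU not at {rate} Hz; preprocess first")
        if ref_t is None:
            ref_t = stream.timestamps
        elif stream.n_samples != ref_t.shape[0]:
            raise ValueError("IMU streams are not synchronized")
        acc = np.stack([stream.channel(c) for c in ("ax", "ay", "az")], axis=1)
        gyr = np.stack([stream.channel(c) for c in ("gx", "gy", "gz")], axis=1)
        cols.extend([acc, np.linalg.norm(acc, axis=1, keepdims=True),
                     gyr, np.linalg.norm(gyr, axis=1, keepdims=True)])
    return ref_t, np.concatenate(cols, axis=1)


def summed_force_bw(bundle: SessionBundle) -> ForceSeries:
    """Summed both-feet force in BW on the force time base."""
    lf, rf = bundle.left_force, bundle.right_force
    if lf.unit != "BW" or rf.unit != "BW":
        raise ValueError("forces must be BW-normalized; preprocess first")
    total = lf.force + rf.force
    return ForceSeries(lf.timestamps.copy(), total[:, None], lf.sample_rate,
                       ("force_total",), unit="BW", body_weight=lf.body_weight)


def make_windows(bundle: SessionBundle, spec: WindowSpec | None = None
                 ) -> WindowedDataset:
    """Cut paired input/target windows from a preprocessed session.

    Windows start at the beginning of the recording and advance by
    ``spec.step`` samples (contiguous by default); a partial tail window is
    dropped. Targets are the summed both-feet force in BW.
    """
    spec = spec or WindowSpec()
    t, X = _input_matrix(bundle, spec.rate)
    target = summed_force_bw(bundle)
    n = min(X.shape[0], target.n_samples)
    W, step = spec.samples, spec.step
    starts = list(range(0, n - W + 1, step))
    inputs = np.stack([X[s:s + W] for s in starts]) if starts else \
        np.empty((0, W, len(CHANNEL_ORDER)))
    targets = np.stack([target.force[s:s + W] for s in starts]) if starts else \
        np.empty((0, W))
    return WindowedDataset(inputs=inputs, targets=targets,
                           channel_order=CHANNEL_ORDER,
                           subject_ids=[bundle.subject_id] * len(starts),
                           start_times=t[np.array(starts, dtype=int)]
                           if starts else np.empty(0))


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _compute_stats(inputs: np.ndarray) -> dict:
    mean = inputs.mean(axis=(0, 1))
    sd = inputs.std(axis=(0, 1))
    degenerate = sd < 1e-8
    if np.any(degenerate):
        log.warning("%d degenerate input channels; SD floored at 1e-8",
                    int(degenerate.sum()))
        sd = np.maximum(sd, 1e-8)
    return {"mean": mean, "sd": sd}


def _apply_stats(inputs: np.ndarray, stats: dict) -> np.ndarray:
    return (inputs - stats["mean"]) / stats["sd"]


def train_bdlstm(train: WindowedDataset, config: TrainingConfig | None = None,
                 window: WindowSpec | None = None) -> ModelArtifact:
    """Train the BD-LSTM on a windowed dataset (z-scored with its own stats)."""
    config = config or TrainingConfig()
    window = window or WindowSpec()
    stats = _compute_stats(train.inputs)
    x = _apply_stats(train.inputs, stats)
    fc = config.fc_units or train.inputs.shape[1]
    model = BiLSTMRegressor(n_channels=train.inputs.shape[2],
                            hidden_units=config.hidden_units,
                            fc_units=fc, seed=config.seed)
    history = model.fit(x, train.targets, epochs=config.epochs,
                        batch_size=config.batch_size, lr=config.learning_rate,
                        seed=config.seed)
    return ModelArtifact(model=model, normalization_stats=stats, config=config,
                         channel_order=train.channel_order, window=window,
                         training_subjects=sorted(set(train.subject_ids)),
                         training_loss=history)


def estimate_grf(artifact: ModelArtifact, bundle: SessionBundle) -> ForceSeries:
    """Predict the summed force series for a session, window by window.

    Non-overlapping windows are predicted independently and concatenated in
    time order into one continuous 100 Hz series.
    """
    spec = WindowSpec(length=artifact.window.length, rate=artifact.window.rate,
                      overlap=0.0)
    t, X = _input_matrix(bundle, spec.rate)
    W = spec.samples
    n_win = X.shape[0] // W
    if n_win == 0:
        raise ValueError("session shorter than one window")
    x = X[:n_win * W].reshape(n_win, W, X.shape[1])
    x = _apply_stats(x, artifact.normalization_stats)
    preds = artifact.model.forward(x)              # (n_win, W)
    series = preds.reshape(-1)
    bw = bundle.mass * 9.81
    return ForceSeries(t[:n_win * W].copy(), series[:, None], spec.rate,
                       ("force_est",), unit="BW", body_weight=bw)


def postprocess_estimate(est: ForceSeries,
                         filter_order: int = 2, filter_fc: float = 15.0,
                         duration_range: tuple[float, float] = CONTACT_DURATION_RANGE
                         ) -> tuple[ForceSeries, list[ge.FootContact]]:
    """Filter, zero and prune an estimated force series; extract LSTM contacts.

    In order: zero-lag low-pass (2nd order, 15 Hz), sub-5 %-BW zeroing,
    contact segmentation by the 5 % BW rule, and forcing to zero any
    segment whose duration falls outside [0.100, 0.500] s. IC/TO of the
    surviving contacts are the run-boundary threshold crossings.
    """
    if est.unit != "BW":
        raise ValueError("postprocess_estimate expects BW force")
    out = butterworth_zero_lag(est, filter_order, filter_fc)
    out = zero_subthreshold(out)
    f = out.force
    lo, hi = duration_range
    contacts: list[ge.FootContact] = []
    for start, stop in _runs(f >= FORCE_THRESHOLD_BW):
        duration = float(out.timestamps[stop - 1] - out.timestamps[start])
        if duration < lo or duration > hi:
            out.values[start:stop] = 0.0
            continue
        ic = ge.GaitEvent("IC", float(out.timestamps[start]), "both", "lstm")
        to = ge.GaitEvent("TO", float(out.timestamps[stop - 1]), "both", "lstm")
        contacts.append(ge.FootContact(ic=ic, to=to, side="both"))
    return out, contacts


# ---------------------------------------------------------------------------
# cross-validation and hyperparameter sweep
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    subject_id: str
    artifact: ModelArtifact
    estimated: ForceSeries          # post-processed
    measured: ForceSeries           # summed measured force, BW
    match: ge.MatchResult
    contacts: pd.DataFrame          # per matched contact metrics


def measured_contacts(bundle: SessionBundle) -> tuple[ForceSeries, list[ge.FootContact]]:
    """Summed measured force and its threshold contacts (running durations only)."""
    total = zero_subthreshold(summed_force_bw(bundle))
    events = ge.detect_events_force(total, side="both")
    lo, hi = CONTACT_DURATION_RANGE
    return total, ge.contacts_from_events(events, min_duration=lo, max_duration=hi)


def _fold_contact_table(est_series: ForceSeries, meas_series: ForceSeries,
                        match: ge.MatchResult,
                        gps: pd.DataFrame | None) -> pd.DataFrame:
    from . import evaluation as ev
    from . import kinetics as kin
    from .signal_io import annotate_speed_grade

    rows = []
    for est_c, meas_c in match.matched:
        meas_st = ev.extract_stance(meas_series, meas_c)
        est_st = ev.extract_stance(est_series, est_c)
        row = {"ic_meas": meas_c.ic.time, "to_meas": meas_c.to.time,
               "ic_est": est_c.ic.time, "to_est": est_c.to.time,
               "contact_time_meas": meas_c.contact_time,
               "contact_time_est": est_c.contact_time,
               "waveform_rmse_bw": ev.rmse_waveform(est_series, meas_c,
                                                    meas_stance=meas_st)}
        for tag, st in (("meas", meas_st), ("est", est_st)):
            try:
                row[f"stance_avg_{tag}"] = kin.stance_average(st)
                row[f"peak_{tag}"] = kin.peak_force(st)
                row[f"impulse_{tag}"] = kin.impulse(st)
                row[f"alr_{tag}"] = kin.average_loading_rate(st)
            except Exception:
                row[f"stance_avg_{tag}"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if gps is not None and len(df):
        bins, classes = annotate_speed_grade(df["ic_meas"].to_numpy(), gps)
        df["velocity_bin"] = bins
        df["grade_class"] = classes
    return df


def loocv(sessions: list[SessionBundle], config: TrainingConfig | None = None,
          window: WindowSpec | None = None,
          preprocessed: bool = False) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation of the GRF estimator.

    For each subject: train on every other subject's windows (normalization
    statistics from those subjects only), estimate on the held-out session,
    post-process and match the resulting contacts against the measured
    force contacts.
    """
    if len(sessions) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    config = config or TrainingConfig()
    window = window or WindowSpec()
    if not preprocessed:
        from .signal_io import preprocess
        sessions = [preprocess(b) for b in sessions]
    datasets = {b.subject_id: make_windows(b, window) for b in sessions}

    results = []
    for held in sessions:
        train_ds = None
        for b in sessions:
            if b.subject_id == held.subject_id:
                continue
            ds = datasets[b.subject_id]
            train_ds = ds if train_ds is None else train_ds.concat(ds)
        artifact = train_bdlstm(train_ds, config, window)
        raw_est = estimate_grf(artifact, held)
        est_series, est_contacts = postprocess_estimate(raw_est)
        meas_series, meas_contacts = measured_contacts(held)
        match = ge.match_events(est_contacts, meas_contacts)
        table = _fold_contact_table(est_series, meas_series, match, held.gps)
        results.append(FoldResult(subject_id=held.subject_id, artifact=artifact,
                                  estimated=est_series, measured=meas_series,
                                  match=match, contacts=table))
    return results


def sweep_hyperparams(sessions: list[SessionBundle],
                      hidden_unit_grid: list[int],
                      window_length_grid: list[float],
                      config: TrainingConfig | None = None,
                      preprocessed: bool = False) -> pd.DataFrame:
    """Seeded grid search over hidden units and window lengths.

    The last subject is the fixed validation split; the table reports the
    validation waveform RMSE per grid point.
    """
    if not hidden_unit_grid or not window_length_grid:
        raise ValueError("grids must be non-empty")
    config = config or TrainingConfig()
    if not preprocessed:
        from .signal_io import preprocess
        sessions = [preprocess(b) for b in sessions]
    train_sessions, val_session = sessions[:-1], sessions[-1]
    rows = []
    for wlen in window_length_grid:
        window = WindowSpec(length=wlen)
        train_ds = None
        for b in train_sessions:
            ds = make_windows(b, window)
            train_ds = ds if train_ds is None else train_ds.concat(ds)
        val_ds = make_windows(val_session, window)
        for h in hidden_unit_grid:
            cfg = TrainingConfig(hidden_units=h, epochs=config.epochs,
                                 batch_size=config.batch_size,
                                 learning_rate=config.learning_rate,
                                 seed=config.seed, fc_units=config.fc_units)
            artifact = train_bdlstm(train_ds, cfg, window)
            x = _apply_stats(val_ds.inputs, artifact.normalization_stats)
            preds = artifact.model.forward(x)
            rmse = float(np.sqrt(np.mean((preds - val_ds.targets) ** 2)))
            rows.append({"hidden_units": h, "window_length_s": wlen,
                         "val_rmse_bw": rmse,
                         "final_train_loss": artifact.training_loss[-1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(artifact: ModelArtifact, path: str | Path) -> Path:
    path = Path(path)
    meta = {"config": vars(artifact.config),
            "window": vars(artifact.window),
            "channel_order": list(artifact.channel_order),
            "training_subjects": artifact.training_subjects,
            "training_loss": artifact.training_loss,
            "n_channels": artifact.model.n_channels,
            "fc_units": artifact.model.fc_units}
    arrays = {f"param.{k}": v for k, v in artifact.model.state_dict().items()}
    arrays["stats.mean"] = artifact.normalization_stats["mean"]
    arrays["stats.sd"] = artifact.normalization_stats["sd"]
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_model(path: str | Path) -> ModelArtifact:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    config = TrainingConfig(**meta["config"])
    window = WindowSpec(**meta["window"])
    model = BiLSTMRegressor(n_channels=meta["n_channels"],
                            hidden_units=config.hidden_units,
                            fc_units=meta["fc_units"], seed=config.seed)
    model.load_state_dict({k[len("param."):]: data[k]
                           for k in data.files if k.startswith("param.")})
    stats = {"mean": data["stats.mean"], "sd": data["stats.sd"]}
    return ModelArtifact(model=model, normalization_stats=stats, config=config,
                         channel_order=tuple(meta["channel_order"]),
                         window=window,
                         training_subjects=meta["training_subjects"],
                         training_loss=meta["training_loss"])
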