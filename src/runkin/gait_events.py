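"""Gait-event detection from insole force and foot-mounted IMU signals.

Three event sources are supported:

* ``force`` — threshold detector on BW-normalized insole force: a contact is
  a contiguous run of samples at or above 5 % BW; IC is the run's first
  sample, TO its last supra-threshold sample.
* ``imu`` — the heuristic foot-IMU detector: IC candidates are prominent
  local minima of the sagittal (x-axis) angular velocity at least 0.500 s
  apart; each candidate is confirmed by a resultant acceleration above
  50 m/s^2 in the 0.005-0.045 s window after the minimum, and IC is placed
  at that window's resultant-acceleration peak. TO is found in the window
  from IC + 0.010 s to half the estimated stride time: the first instant
  gravity-compensated vertical acceleration exceeds 3 g, falling back to the
  window's vertical-acceleration maximum when no crossing occurs.
* ``lstm`` — threshold events on the post-processed estimated force
  (see :mod:`runkin.grf_lstm`).

Estimated contacts are matched to measured ones greedily by nearest IC time;
a pair is kept only when the IC discrepancy is within half the measured
contact time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import FORCE_THRESHOLD_BW, ForceSeries, TimeSeries

log = logging.getLogger(__name__)

#: Minimum separation between accepted x-gyro minima (one per stride).
MIN_STRIDE_SEPARATION_S = 0.500
#: Prominence floor for x-gyro minima, rad/s (suppresses noise minima).
GYRO_MIN_PROMINENCE = 0.5
#: IC confirmation window after the gyro minimum, seconds.
IC_SEARCH_WINDOW = (0.005, 0.045)
#: Resultant acceleration a candidate must exceed to confirm IC, m/s^2.
IC_ACCEL_THRESHOLD = 50.0
#: TO search starts this long after IC.
TO_SEARCH_START_S = 0.010
#: Vertical-acceleration threshold (3 g) for the toe-off rule.
TO_ACCEL_THRESHOLD = 3.0 * 9.81


@dataclass(frozen=True)
class GaitEvent:
    kind: str   # "IC" | "TO"
    time: float
    side: str   # "left" | "right"
    source: str  # "force" | "imu" | "lstm"


@dataclass
class FootContact:
    ic: GaitEvent
    to: GaitEvent
    side: str
    velocity_bin: float | None = None
    grade_class: str | None = None

    def __post_init__(self) -> None:
        if self.to.time <= self.ic.time:
            raise ValueError("TO must follow IC")

    @property
    def contact_time(self) -> float:
        return self.to.time - self.ic.time


# ---------------------------------------------------------------------------
# force-threshold events
# ---------------------------------------------------------------------------

def detect_events_force(force: ForceSeries, side: str = "left",
                        threshold: float = FORCE_THRESHOLD_BW,
                        source: str = "force") -> list[GaitEvent]:
    """IC/TO at the boundaries of each supra-threshold run of a BW force series."""
    if force.unit != "BW":
        raise ValueError("detect_events_force expects BW-normalized force")
    from .signal_io import _runs

    f = force.force
    events: list[GaitEvent] = []
    for start, stop in _runs(f >= threshold):
        events.append(GaitEvent("IC", float(force.timestamps[start]), side, source))
        events.append(GaitEvent("TO", float(force.timestamps[stop - 1]), side, source))
    return events


def contacts_from_events(events: list[GaitEvent],
                         min_duration: float = 0.0,
                         max_duration: float = np.inf) -> list[FootContact]:
    """Pair alternating IC/TO events into contacts, optionally duration-gated."""
    contacts = []
    pending: GaitEvent | None = None
    for ev in sorted(events, key=lambda e: e.time):
        if ev.kind == "IC":
            pending = ev
        elif pending is not None:
            duration = ev.time - pending.time
            if min_duration <= duration <= max_duration:
                contacts.append(FootContact(ic=pending, to=ev, side=ev.side))
            pending = None
    return contacts


# ---------------------------------------------------------------------------
# foot-IMU heuristic
# ---------------------------------------------------------------------------

def _gyro_minima(foot_imu: TimeSeries) -> np.ndarray:
    """Indices of candidate x-gyro minima, >= 0.500 s apart (deeper one wins)."""
    gx = foot_imu.channel("gx")
    distance = max(1, int(round(MIN_STRIDE_SEPARATION_S * foot_imu.sample_rate)))
    minima, _ = sps.find_peaks(-gx, prominence=GYRO_MIN_PROMINENCE,
                               distance=distance)
    return minima


def detect_ic_imu(foot_imu: TimeSeries, side: str = "left") -> list[GaitEvent]:
    """Initial contacts from the foot IMU (gyro-minimum + acceleration spike)."""
    events, _ = _detect_ic_with_candidates(foot_imu, side)
    return events


def _detect_ic_with_candidates(foot_imu: TimeSeries, side: str
                               ) -> tuple[list[GaitEvent], np.ndarray]:
    for ch in ("gx", "ax", "ay", "az"):
        if ch not in foot_imu.channel_names:
            raise ValueError(f"foot IMU stream lacks channel {ch!r}")
    t = foot_imu.timestamps
    acc = foot_imu.values[:, [foot_imu.channel_names.index(c)
                              for c in ("ax", "ay", "az")]]
    resultant = np.linalg.norm(acc, axis=1)

    minima = _gyro_minima(foot_imu)
    events: list[GaitEvent] = []
    kept_minima = []
    for m in minima:
        lo = np.searchsorted(t, t[m] + IC_SEARCH_WINDOW[0])
        hi = np.searchsorted(t, t[m] + IC_SEARCH_WINDOW[1], side="right")
        if hi <= lo:
            continue
        window = resultant[lo:hi]
        if np.max(window) > IC_ACCEL_THRESHOLD:
            peak = lo + int(np.argmax(window))
            events.append(GaitEvent("IC", float(t[peak]), side, "imu"))
            kept_minima.append(m)
    return events, np.asarray(kept_minima, dtype=int)


def detect_to_imu(foot_imu: TimeSeries, ic_events: list[GaitEvent],
                  stride_time_estimates: np.ndarray) -> list[GaitEvent]:
    """Toe offs for each IC via the 3 g / vertical-acceleration-maximum rule."""
    t = foot_imu.timestamps
    az = foot_imu.channel("az")
    ic_times = np.array([e.time for e in ic_events])
    events: list[GaitEvent] = []
    for k, ic in enumerate(ic_events):
        end = ic.time + 0.5 * float(stride_time_estimates[k])
        if k + 1 < ic_times.size:  # clamp before the next IC
            end = min(end, ic_times[k + 1] - 1.0 / foot_imu.sample_rate)
        lo = np.searchsorted(t, ic.time + TO_SEARCH_START_S)
        hi = np.searchsorted(t, end, side="right")
        if hi <= lo:
            log.warning("empty toe-off window after IC at %.3f s; contact skipped",
                        ic.time)
            continue
        window = az[lo:hi]
        crossing = np.flatnonzero(window > TO_ACCEL_THRESHOLD)
        idx = lo + (int(crossing[0]) if crossing.size else int(np.argmax(window)))
        events.append(GaitEvent("TO", float(t[idx]), ic.side, "imu"))
    return events


def detect_events_imu(foot_imu: TimeSeries, side: str = "left"
                      ) -> tuple[list[GaitEvent], list[GaitEvent]]:
    """Full heuristic: ICs, then TOs with stride times from gyro-minima spacing."""
    ics, minima = _detect_ic_with_candidates(foot_imu, side)
    if not ics:
        return [], []
    t_min = foot_imu.timestamps[minima]
    if t_min.size > 1:
        gaps = np.diff(t_min)
        strides = np.append(gaps, gaps[-1])
    else:
        strides = np.array([2.0 * MIN_STRIDE_SEPARATION_S])
    tos = detect_to_imu(foot_imu, ics, strides)
    return ics, tos


# ---------------------------------------------------------------------------
# contact matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    matched: list[tuple[FootContact, FootContact]]  # (estimated, measured)
    removed_estimated: list[tuple[FootContact, str]]
    removed_measured: list[tuple[FootContact, str]]


def match_events(estimated: list[FootContact],
                 measured: list[FootContact]) -> MatchResult:
    """Greedy nearest-IC one-to-one matching with the half-contact-time gate.

    A candidate pair survives only when |IC_est - IC_meas| <= half the
    measured contact time; unmatched contacts on either side are reported
    with the reason for their removal.
    """
    est_t = np.array([c.ic.time for c in estimated])
    meas_t = np.array([c.ic.time for c in measured])
    cand: list[tuple[float, int, int]] = []
    if est_t.size and meas_t.size:
        order = np.argsort(meas_t)
        meas_sorted = meas_t[order]
        pos = np.searchsorted(meas_sorted, est_t)
        for i in range(est_t.size):
            for p in (pos[i] - 1, pos[i]):
                if 0 <= p < meas_sorted.size:
                    j = int(order[p])
                    cand.append((abs(est_t[i] - meas_t[j]), i, j))
    cand.sort()

    used_e: set[int] = set()
    used_m: set[int] = set()
    matched, removed_e = [], []
    for d, i, j in cand:
        if i in used_e or j in used_m:
            continue
        if d <= 0.5 * measured[j].contact_time:
            matched.append((estimated[i], measured[j]))
            used_e.add(i)
            used_m.add(j)
    for i, c in enumerate(estimated):
        if i not in used_e:
            removed_e.append((c, "no measured IC within half contact time"))
    removed_m = [(c, "unmatched") for j, c in enumerate(measured)
                 if j not in used_m]
    return MatchResult(matched=matched, removed_estimated=removed_e,
                       removed_measured=removed_m)
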