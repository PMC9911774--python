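"""Discrete kinetic and spatiotemporal variables from stance-phase force.

All forces are body-weight normalized (BW). A stance phase is the sampled
force between initial contact (IC) and toe off (TO) of one footfall; from it
we compute the stance average force, peak force, impulse (time integral),
and the average loading rate (ALR) — the force/time slope over the middle
60 % of the interval from IC to the impact peak. Stride frequency comes
from successive same-foot IC times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import InsufficientDataError

#: Impact peaks are searched in the first 40 % of stance.
IMPACT_SEARCH_FRACTION = 0.40
#: Fallback impact-peak location when no early local maximum exists.
IMPACT_FALLBACK_FRACTION = 0.13
#: Minimum prominence (BW) for a local maximum to count as an impact peak.
IMPACT_PROMINENCE_BW = 0.05


@dataclass
class StancePhase:
    """Force samples of one foot contact, IC to TO, BW-normalized."""

    times: np.ndarray
    force: np.ndarray
    side: str | None = None
    contact: object | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.times.shape != self.force.shape:
            raise ValueError("times and force must have equal shapes")

    @property
    def contact_time(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class KineticSummary:
    stance_average: float  # BW
    peak: float            # BW
    impulse: float         # BW*s
    alr: float             # BW/s
    contact_time: float    # s


def stance_average(stance: StancePhase) -> float:
    """Time-weighted mean force over [IC, TO] (trapezoidal integral / duration)."""
    if stance.times.size < 3:
        raise InsufficientDataError("stance average needs >= 3 samples")
    return impulse(stance) / stance.contact_time


def peak_force(stance: StancePhase) -> float:
    if stance.times.size < 1:
        raise InsufficientDataError("empty stance phase")
    return float(np.max(stance.force))


def impulse(stance: StancePhase) -> float:
    """Trapezoidal integral of force over the stance interval, BW*s."""
    if stance.times.size < 2:
        raise InsufficientDataError("impulse needs >= 2 samples")
    return float(np.trapezoid(stance.force, stance.times))


def find_impact_peak(stance: StancePhase) -> tuple[int, bool]:
    """Index of the impact peak and whether the 13 %-of-stance fallback fired.

    The impact peak is the first local maximum with prominence >= 0.05 BW in
    the first 40 % of stance. Without one (e.g. a smooth single-bell
    waveform) the sample nearest 13 % of contact time is returned, flagged.
    """
    n = stance.times.size
    if n < 10:
        raise InsufficientDataError("impact-peak search needs >= 10 samples")
    limit = int(np.floor(IMPACT_SEARCH_FRACTION * (n - 1)))
    peaks, _ = sps.find_peaks(stance.force, prominence=IMPACT_PROMINENCE_BW)
    early = peaks[peaks <= limit]
    if early.size:
        return int(early[0]), False
    return int(round(IMPACT_FALLBACK_FRACTION * (n - 1))), True


def average_loading_rate(stance: StancePhase) -> float:
    """Least-squares force/time slope over the middle 60 % of IC->impact peak.

    With fewer than 3 samples inside [IC + 0.2*D, IC + 0.8*D]
    (D = impact-peak time - IC), the slope of the two samples nearest that
    span is used instead.
    """
    idx, _ = find_impact_peak(stance)
    t0 = stance.times[0]
    delta = stance.times[idx] - t0
    if delta <= 0:
        raise ValueError("impact peak does not follow initial contact")
    lo, hi = t0 + 0.2 * delta, t0 + 0.8 * delta
    inside = (stance.times >= lo) & (stance.times <= hi)
    if np.count_nonzero(inside) >= 3:
        t, f = stance.times[inside], stance.force[inside]
        return float(np.polyfit(t, f, 1)[0])
    center = 0.5 * (lo + hi)
    order = np.argsort(np.abs(stance.times - center))[:2]
    i, j = np.sort(order)
    dt = stance.times[j] - stance.times[i]
    return float((stance.force[j] - stance.force[i]) / dt)


def summarize(stance: StancePhase) -> KineticSummary:
    return KineticSummary(stance_average=stance_average(stance),
                          peak=peak_force(stance),
                          impulse=impulse(stance),
                          alr=average_loading_rate(stance),
                          contact_time=stance.contact_time)


def stride_frequency(ic_times: np.ndarray) -> float:
    """Strides per minute of one foot: 60 / median inter-IC interval."""
    ic_times = np.sort(np.asarray(ic_times, dtype=float))
    if ic_times.size < 3:
        raise InsufficientDataError("stride frequency needs >= 3 ICs per foot")
    return 60.0 / float(np.median(np.diff(ic_times)))


def stride_frequency_both_feet(left_ics: np.ndarray, right_ics: np.ndarray) -> float:
    """Mean of per-foot stride frequencies; one foot suffices if the other lacks ICs."""
    freqs = []
    for ics in (left_ics, right_ics):
        try:
            freqs.append(stride_frequency(ics))
        except InsufficientDataError:
            pass
    if not freqs:
        raise InsufficientDataError("neither foot has enough ICs")
    return float(np.mean(freqs))
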