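import numpy as np
import pytest

from runkin import signal_io as sio
from runkin import synthetic_data as sd


def noise_free_profile(**kwargs) -> sd.SubjectProfile:
    """Subject with all sensor noise switched off (deterministic channels)."""
    noise = {f"{loc}.{ch}": 0.0
             for loc in ("left", "right", "sacrum")
             for ch in sio.IMU_CHANNELS}
    return sd.SubjectProfile(subject_id=kwargs.pop("subject_id", "NF"),
                             noise_sd_vector=noise, **kwargs)


@pytest.fixture(scope="session")
def default_profile() -> sd.SubjectProfile:
    return sd.SubjectProfile(subject_id="S00")


@pytest.fixture(scope="session")
def session30(default_profile) -> sio.SessionBundle:
    """30 s steady run at 3.0 m/s, default sensor noise, seed 0."""
    return sd.simulate_session(default_profile, sd.steady_course(30.0, 3.0), seed=0)


@pytest.fixture(scope="session")
def clean30(session30) -> sio.SessionBundle:
    return sio.preprocess(session30)


@pytest.fixture(scope="session")
def session30_quiet() -> sio.SessionBundle:
    """Noise-free 30 s session for exact-recovery checks."""
    return sd.simulate_session(noise_free_profile(), sd.steady_course(30.0, 3.0),
                               seed=0)


def truth_times(bundle, event: str, side: str) -> np.ndarray:
    t = bundle.truth
    return t[(t["event"] == event) & (t["side"] == side)]["time_s"].to_numpy()


def nearest_errors(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Error of the detected event nearest to each truth event."""
    detected = np.sort(np.asarray(detected))
    idx = np.clip(np.searchsorted(detected, truth), 1, len(detected) - 1)
    left, right = detected[idx - 1], detected[idx]
    return np.where(np.abs(truth - left) < np.abs(truth - right),
                    left - truth, right - truth)
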