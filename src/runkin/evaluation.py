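"""Agreement analysis between estimated and measured gait variables.

Implements the statistical machinery for validating estimated contact times
and kinetic variables against the insole standard: per-contact waveform
RMSE, aggregation into (subject, velocity bin, grade class) cells with a
minimum-10-footfall inclusion rule, Bland-Altman bias with 95 % limits of
agreement, and ordinary least squares with the squared Pearson correlation
and its strength category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .gait_events import FootContact
from .kinetics import StancePhase
from .signal_io import ForceSeries, InsufficientDataError

#: Cells with fewer footfalls than this are excluded from reports.
MIN_FOOTFALLS_PER_BIN = 10


@dataclass
class AgreementResult:
    bias: float        # mean(estimated - measured)
    loa_low: float     # bias - 1.96 SD
    loa_high: float    # bias + 1.96 SD
    r_squared: float
    slope: float
    rmse: float
    n: int


def extract_stance(series: ForceSeries, contact: FootContact) -> StancePhase:
    """Force samples of ``series`` over a contact's [IC, TO] interval."""
    t = series.timestamps
    i0 = np.searchsorted(t, contact.ic.time)
    i1 = np.searchsorted(t, contact.to.time, side="right")
    return StancePhase(times=t[i0:i1], force=series.force[i0:i1],
                       side=contact.side, contact=contact)


def rmse_waveform(est_series: ForceSeries, measured_contact: FootContact,
                  meas_series: ForceSeries | None = None,
                  meas_stance: StancePhase | None = None) -> float:
    """RMSE over the measured stance interval, paired by absolute timestamp.

    The estimated series is sampled at the measured stance timestamps
    (zero where no estimate exists).
    """
    if meas_stance is None:
        if meas_series is None:
            raise ValueError("provide the measured series or stance")
        meas_stance = extract_stance(meas_series, measured_contact)
    if meas_stance.times.size == 0:
        raise ValueError("measured stance has no samples")
    t_est = est_series.timestamps
    idx = np.searchsorted(t_est, meas_stance.times)
    est = np.zeros_like(meas_stance.force)
    half_dt = 0.5 / est_series.sample_rate
    for k, (tt, i) in enumerate(zip(meas_stance.times, idx)):
        for j in (i - 1, i):
            if 0 <= j < t_est.size and abs(t_est[j] - tt) <= half_dt:
                est[k] = est_series.force[j]
                break
    diff = est - meas_stance.force
    return float(np.sqrt(np.mean(diff * diff)))


def bland_altman(estimated: np.ndarray, measured: np.ndarray
                 ) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high): mean difference +- 1.96 sample SD (n-1)."""
    estimated = np.asarray(estimated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimated.shape != measured.shape:
        raise ValueError("inputs must have equal length")
    if estimated.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    diff = estimated - measured
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def linear_agreement(estimated: np.ndarray, measured: np.ndarray
                     ) -> tuple[float, float]:
    """(r_squared, slope) of the OLS fit of estimated on measured."""
    estimated = np.asarray(estimated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimated.size != measured.size or estimated.size < 3:
        raise InsufficientDataError("regression needs >= 3 paired values")
    if np.std(measured) == 0:
        raise ValueError("measured values have zero variance; correlation undefined")
    fit = sstats.linregress(measured, estimated)
    return float(fit.rvalue ** 2), float(fit.slope)


def classify_correlation(r_squared: float) -> str:
    """strong >= 0.8 > moderate >= 0.5 > weak >= 0.3 > below-weak."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("r_squared must lie in [0, 1]")
    if r_squared >= 0.8:
        return "strong"
    if r_squared >= 0.5:
        return "moderate"
    if r_squared >= 0.3:
        return "weak"
    return "below-weak"


def agreement(estimated: np.ndarray, measured: np.ndarray) -> AgreementResult:
    """Full agreement summary for one estimated-vs-measured variable."""
    bias, lo, hi = bland_altman(estimated, measured)
    r2, slope = linear_agreement(estimated, measured)
    diff = np.asarray(estimated, float) - np.asarray(measured, float)
    return AgreementResult(bias=bias, loa_low=lo, loa_high=hi, r_squared=r2,
                           slope=slope, rmse=float(np.sqrt(np.mean(diff ** 2))),
                           n=int(diff.size))


def aggregate_bins(contacts: pd.DataFrame, subject_id: str | None = None,
                   min_footfalls: int = MIN_FOOTFALLS_PER_BIN) -> pd.DataFrame:
    """Per-(subject, velocity bin, grade class) means of each paired variable.

    ``contacts`` is a per-footfall table with ``velocity_bin`` and
    ``grade_class`` columns plus paired ``*_est`` / ``*_meas`` variable
    columns (as produced by the LOOCV). Footfalls without a velocity bin and
    cells with fewer than 10 footfalls are excluded. RMSE-type columns
    (e.g. ``waveform_rmse_bw``) are averaged as root-mean-squares.
    """
    df = contacts.copy()
    if subject_id is not None and "subject_id" not in df:
        df["subject_id"] = subject_id
    df = df[df["velocity_bin"].notna()]
    keys = [k for k in ("subject_id", "velocity_bin", "grade_class") if k in df]
    rows = []
    for group_key, grp in df.groupby(keys):
        if len(grp) < min_footfalls:
            continue
        row = dict(zip(keys, np.atleast_1d(group_key)))
        row["n_footfalls"] = len(grp)
        for col in grp.columns:
            if col in keys or not np.issubdtype(grp[col].dtype, np.number):
                continue
            if "rmse" in col:
                row[col] = float(np.sqrt(np.mean(grp[col].to_numpy() ** 2)))
            else:
                row[col] = float(grp[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def agreement_report(binned: pd.DataFrame,
                     variables: tuple[str, ...] = ("contact_time", "stance_avg",
                                                   "peak", "impulse", "alr")
                     ) -> pd.DataFrame:
    """Agreement statistics per variable across aggregated bins."""
    rows = []
    for var in variables:
        est_col, meas_col = f"{var}_est", f"{var}_meas"
        if est_col not in binned or meas_col not in binned:
            continue
        ok = binned[[est_col, meas_col]].dropna()
        if len(ok) < 3:
            continue
        res = agreement(ok[est_col].to_numpy(), ok[meas_col].to_numpy())
        rows.append({"variable": var, "n_bins": res.n, "bias": res.bias,
                     "loa_low": res.loa_low, "loa_high": res.loa_high,
                     "r2": res.r_squared,
                     "r2_class": classify_correlation(min(res.r_squared, 1.0)),
                     "slope": res.slope, "rmse": res.rmse})
    return pd.DataFrame(rows)
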