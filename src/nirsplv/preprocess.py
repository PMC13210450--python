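"""Preprocessing chain for concentration time series.

Order of operations (applied to the continuous record, never per
epoch): MBLL inversion (see :mod:`nirsplv.mbll`), anti-aliased
resampling from the device rate 8.138 Hz to 2 Hz, zero-phase band-pass
filtering (3rd-order Butterworth, 0.005–0.05 Hz, forward–backward),
then epoching to [−1, 61) s around each task onset with baseline
correction over [−1, 0] s.

Numerical conventions: the 8.138 → 2 Hz conversion uses the rational
polyphase ratio 1000/4069 with a Kaiser anti-aliasing filter; epochs
are a half-open window of exactly 124 samples at 2 Hz whose onset
sample is the first sample at or after the marker time; the baseline
statistic is the arithmetic mean of the samples with −1 ≤ t ≤ 0.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet, HemoSeries
from .errors import EmptyEpochSetError, InvalidArgumentError
from .paradigm import ParadigmSchedule

logger = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.005, 0.05)
DEFAULT_FILTER_ORDER = 3
DEFAULT_EPOCH_WINDOW_S = (-1.0, 61.0)
DEFAULT_BASELINE_WINDOW_S = (-1.0, 0.0)
DEFAULT_CV_MAX = 0.15


# --------------------------------------------------------------------------
# array-level primitives (leading axes arbitrary, time on the last axis)


def resample_array(x: np.ndarray, rate_hz: float, target_hz: float) -> np.ndarray:
    """Polyphase anti-aliased rate conversion along the last axis."""
    if target_hz >= rate_hz:
        raise InvalidArgumentError(
            f"target rate {target_hz} Hz must be below the original {rate_hz} Hz"
        )
    frac = Fraction(target_hz / rate_hz).limit_denominator(10_000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def bandpass_sos(
    low_hz: float, high_hz: float, rate_hz: float, order: int = DEFAULT_FILTER_ORDER
) -> np.ndarray:
    if not 0 < low_hz < high_hz < rate_hz / 2:
        raise InvalidArgumentError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist"
        )
    return sps.butter(order, (low_hz, high_hz), btype="band", fs=rate_hz, output="sos")


def bandpass_array(
    x: np.ndarray,
    rate_hz: float,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-pass.

    Edge handling: odd-symmetric reflection padding, 3× the slow-edge
    time scale of the filter, capped at the record length.
    """
    sos = bandpass_sos(low_hz, high_hz, rate_hz, order)
    padlen = min(x.shape[-1] - 1, int(3.0 * rate_hz / low_hz))
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


# --------------------------------------------------------------------------
# series-level operations


def resample(series: HemoSeries, target_hz: float = 2.0) -> HemoSeries:
    """Resample to ``target_hz`` (marker times are in seconds and carry over)."""
    hbo = resample_array(series.hbo, series.rate_hz, target_hz)
    hbr = (
        resample_array(series.hbr, series.rate_hz, target_hz)
        if series.hbr is not None
        else None
    )
    return series.copy_with(hbo=hbo, hbr=hbr, rate_hz=target_hz)


def bandpass(
    series: HemoSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> HemoSeries:
    """Zero-phase band-pass; tags the series with its pass band."""
    hbo = bandpass_array(series.hbo, series.rate_hz, low_hz, high_hz, order)
    hbr = (
        bandpass_array(series.hbr, series.rate_hz, low_hz, high_hz, order)
        if series.hbr is not None
        else None
    )
    return series.copy_with(hbo=hbo, hbr=hbr, band_hz=(low_hz, high_hz))


def drop_noisy_channels(
    raw_baseline: np.ndarray, cv: np.ndarray, cv_max: float = DEFAULT_CV_MAX
) -> np.ndarray:
    """Channel QC mask: keep channels with positive baseline intensity and
    coefficient of variation within ``cv_max`` at both wavelengths.

    Returns a boolean keep-mask over channels and logs rejections. The
    numeric criterion is configurable; it stands in for the study's
    qualitative low-SNR exclusion rule.
    """
    keep = np.all(raw_baseline > 0, axis=-1) & np.all(cv <= cv_max, axis=-1)
    for ch in np.nonzero(~keep)[0]:
        logger.warning("channel index %d rejected by QC (cv_max=%g)", ch, cv_max)
    return keep


def epoch_and_baseline(
    series: HemoSeries,
    schedule: ParadigmSchedule,
    window_s: tuple[float, float] = DEFAULT_EPOCH_WINDOW_S,
    baseline_s: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S,
    subject: int = 1,
) -> EpochSet:
    """Cut per-trial epochs around task onsets and baseline-correct.

    The epoch window is half-open ([−1, 61) s → 124 samples at 2 Hz);
    epochs whose window falls outside the record are dropped with a
    logged reason. Baseline correction subtracts the per-epoch,
    per-channel mean over ``baseline_s`` (closed window).
    """
    fs = series.rate_hz
    n_pre = int(round(-window_s[0] * fs))
    n_len = int(round((window_s[1] - window_s[0]) * fs))
    n = series.n_samples

    rows, dropped, chunks = [], [], []
    for trial in schedule.trials.itertuples(index=False):
        onset = trial.task_onset_s
        i_on = math.ceil(onset * fs - 1e-9)
        start = i_on - n_pre
        stop = start + n_len
        if start < 0 or stop > n:
            reason = "insufficient pre-onset data" if start < 0 else "record ends early"
            logger.warning(
                "dropping epoch (%s trial %d): %s", trial.condition, trial.trial, reason
            )
            dropped.append(
                {"condition": trial.condition, "trial": trial.trial, "reason": reason}
            )
            continue
        chunks.append(series.hbo[:, start:stop])
        rows.append(
            {"subject": subject, "condition": trial.condition, "trial": trial.trial}
        )
    if not rows:
        raise EmptyEpochSetError("no trial produced a valid epoch")

    data = np.stack(chunks)  # (epochs, channels, times)
    times = window_s[0] + np.arange(n_len) / fs
    bl = (times >= baseline_s[0] - 1e-9) & (times <= baseline_s[1] + 1e-9)
    if not bl.any():
        raise InvalidArgumentError("baseline window contains no samples")
    data = data - data[:, :, bl].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        index=pd.DataFrame(rows),
        times=times,
        rate_hz=fs,
        layout=series.layout,
        baseline_window_s=baseline_s,
        dropped=pd.DataFrame(dropped) if dropped else None,
    )


def preprocess(
    series: HemoSeries,
    schedule: ParadigmSchedule,
    target_hz: float = 2.0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> HemoSeries:
    """Resample then band-pass the continuous record (epoching is separate
    so connectivity can consume the same filtered continuous series)."""
    out = resample(series, target_hz) if target_hz < series.rate_hz else series
    out = bandpass(out, band_hz[0], band_hz[1], order)
    if schedule is not None:
        out.markers = schedule.events.copy()
    return out
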