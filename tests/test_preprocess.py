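"""Resampling, zero-phase filtering and epoching contracts."""

import numpy as np
import pytest
from scipy import signal as sps

from nirsplv import bandpass, epoch_and_baseline, generate_paradigm, resample
from nirsplv.errors import InvalidArgumentError
from nirsplv.preprocess import bandpass_sos


def _sine(f, fs, dur, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(np.sin(2 * np.pi * f * t), (n_ch, 1))


def test_resample_sample_count(make_series):
    s = make_series(np.zeros((2, int(600 * 8.138))), rate_hz=8.138)
    out = resample(s, 2.0)
    assert abs(out.n_samples - 1200) <= 1


def test_resample_preserves_passband_sine(make_series):
    s = make_series(_sine(0.02, 8.138, 600), rate_hz=8.138)
    out = resample(s, 2.0)
    # compare against the analytic sinusoid on the new grid, away from edges
    t = np.arange(out.n_samples) / 2.0
    ref = np.sin(2 * np.pi * 0.02 * t)
    sl = slice(100, out.n_samples - 100)
    amp = np.ptp(out.hbo[0, sl]) / np.ptp(ref[sl])
    assert amp == pytest.approx(1.0, abs=0.01)


def test_resample_keeps_dc_and_rejects_upsampling(make_series):
    s = make_series(np.full((2, 1000), 3.7), rate_hz=8.138)
    out = resample(s, 2.0)
    # constant preserved away from the anti-aliasing filter's edge transients
    assert np.allclose(out.hbo[:, 20:-20], 3.7, atol=1e-3)
    with pytest.raises(InvalidArgumentError):
        resample(s, 16.0)


def test_bandpass_midband_zero_phase(make_series):
    s = make_series(_sine(0.02, 2.0, 4000), rate_hz=2.0, band=None)
    out = bandpass(s)
    x, y = s.hbo[0], out.hbo[0]
    sl = slice(2000, 6000)
    ratio = np.sqrt(np.mean(y[sl] ** 2) / np.mean(x[sl] ** 2))
    assert ratio >= 0.9
    lags = sps.correlation_lags(len(x[sl]), len(y[sl]))
    xc = sps.correlate(x[sl], y[sl])
    assert lags[np.argmax(xc)] == 0  # zero-phase: peak correlation at zero lag
    assert out.band_hz == (0.005, 0.05)


def test_bandpass_removes_dc(make_series):
    s = make_series(np.full((2, 2400), 5.0), rate_hz=2.0, band=None)
    out = bandpass(s)
    assert np.abs(out.hbo.mean()) < 1e-3


def test_bandpass_stopband_matches_butterworth_response(make_series):
    """0.3 Hz sinusoid attenuation equals the squared (two-pass)
    order-3 Butterworth magnitude at 0.3 Hz within 5%."""
    f0, fs, dur = 0.3, 2.0, 4000.0
    s = make_series(_sine(f0, fs, dur), rate_hz=fs, band=None)
    out = bandpass(s)
    t = np.arange(s.n_samples) / fs
    sl = slice(int(1000 * fs), int(3000 * fs))
    # lock-in amplitude estimate at f0 over the central window
    ref = np.exp(2j * np.pi * f0 * t[sl])
    amp = 2 * np.abs(np.mean(out.hbo[0, sl] * ref))
    _, h = sps.sosfreqz(bandpass_sos(0.005, 0.05, fs), worN=[2 * np.pi * f0 / fs])
    expected = np.abs(h[0]) ** 2  # forward-backward -> magnitude squared
    assert expected <= 0.1
    assert amp == pytest.approx(expected, rel=0.05)


def test_bandpass_band_validation(make_series):
    s = make_series(np.zeros((2, 100)), rate_hz=2.0)
    with pytest.raises(InvalidArgumentError):
        bandpass(s, 0.05, 1.5)


def test_epoching_counts_window_and_baseline(layout):
    rng = np.random.default_rng(0)
    sched = generate_paradigm(10, order_seed=0)
    from nirsplv.containers import HemoSeries

    n = int(sched.session_span_s * 2)
    series = HemoSeries(hbo=rng.normal(size=(15, n)), rate_hz=2.0, layout=layout)
    ep = epoch_and_baseline(series, sched)
    assert ep.n_epochs == 20
    assert ep.data.shape[2] == 124  # [-1, 61) s at 2 Hz
    for cond in ("OOC", "SOC"):
        assert (ep.index["condition"] == cond).sum() == 10
    bl = (ep.times >= -1.0 - 1e-9) & (ep.times <= 1e-9)
    assert np.max(np.abs(ep.data[:, :, bl].mean(axis=2))) < 1e-12


def test_epoch_without_pre_window_dropped(layout):
    rng = np.random.default_rng(1)
    sched = generate_paradigm(3, order_seed=0, lead_in_s=0.0, tail_s=5.0)
    from nirsplv.containers import HemoSeries

    n = int(sched.session_span_s * 2)
    series = HemoSeries(hbo=rng.normal(size=(15, n)), rate_hz=2.0, layout=layout)
    ep = epoch_and_baseline(series, sched)
    assert ep.n_epochs == 5  # first trial (onset 0.5 s) lacks 1 s of pre-data
    assert ep.dropped is not None and len(ep.dropped) == 1


def test_epochs_are_views_of_the_continuous_filtered_record(layout):
    """Filtering happens on the continuous record; epochs must equal
    slices of it (up to baseline subtraction), never per-epoch filtering."""
    rng = np.random.default_rng(2)
    sched = generate_paradigm(4, order_seed=0)
    from nirsplv.containers import HemoSeries

    n = int(sched.session_span_s * 2)
    series = HemoSeries(hbo=rng.normal(size=(15, n)), rate_hz=2.0, layout=layout)
    filt = bandpass(series)
    ep = epoch_and_baseline(filt, sched)
    trial = sched.trials.iloc[3]
    i_on = int(np.ceil(trial["task_onset_s"] * 2.0 - 1e-9))
    sl = filt.hbo[:, i_on - 2 : i_on - 2 + 124]
    k = ep.index[
        (ep.index["condition"] == trial["condition"]) & (ep.index["trial"] == trial["trial"])
    ].index[0]
    centered = sl - ep.data[k]
    # difference is a per-channel constant (the subtracted baseline mean)
    assert np.max(np.ptp(centered, axis=1)) < 1e-12


def test_resample_then_bandpass_matches_analytic_signal(make_series):
    """A passband sinusoid survives the 8.138->2 Hz + band-pass chain
    within 2% RMS once two filter time constants are discarded."""
    fs, f0 = 8.138, 0.02
    dur = 3000.0
    s = make_series(_sine(f0, fs, dur), rate_hz=fs, band=None)
    out = bandpass(resample(s, 2.0))
    t = np.arange(out.n_samples) / 2.0
    _, h = sps.sosfreqz(bandpass_sos(0.005, 0.05, 2.0), worN=[2 * np.pi * f0 / 2.0])
    gain = np.abs(h[0]) ** 2
    ref = gain * np.sin(2 * np.pi * f0 * t)
    edge = int(2 * (1 / 0.005) * 2.0)  # two time constants of the slow edge
    sl = slice(edge, out.n_samples - edge)
    err = np.sqrt(np.mean((out.hbo[0, sl] - ref[sl]) ** 2) / np.mean(ref[sl] ** 2))
    assert err < 0.02
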