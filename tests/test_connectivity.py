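"""Hilbert phases, PLV, ROI aggregation, seed profile, binarization."""

import numpy as np
import pandas as pd
import pytest

from nirsplv import (
    CouplingSpec,
    NoiseSpec,
    ResponseSpec,
    binarize,
    instantaneous_phase,
    plv,
    plv_matrix,
    roi_mean_connectivity,
    seed_profile,
    simulate_hemodynamics,
)
from nirsplv.connectivity import ConnectivityMatrix
from nirsplv.errors import InvalidArgumentError, SegmentLengthError
from nirsplv.preprocess import bandpass, preprocess


def _sine_series(make_series, rows, fs=2.0):
    return make_series(rows, rate_hz=fs, band=(0.005, 0.05))


def test_phase_slope_of_sine(make_series):
    fs, f0, dur = 2.0, 0.02, 2000.0
    t = np.arange(int(dur * fs)) / fs
    s = _sine_series(make_series, np.tile(np.sin(2 * np.pi * f0 * t), (2, 1)), fs)
    ph = instantaneous_phase(s, edge_trim_s=50.0)
    slope = np.diff(np.unwrap(ph.phase[0])).mean() * fs  # rad/s
    assert slope == pytest.approx(2 * np.pi * f0, rel=0.01)


def test_cos_vs_sin_quadrature(make_series):
    fs, f0 = 2.0, 0.02
    t = np.arange(4000) / fs
    rows = np.vstack([np.cos(2 * np.pi * f0 * t), np.sin(2 * np.pi * f0 * t)])
    ph = instantaneous_phase(_sine_series(make_series, rows, fs), edge_trim_s=100.0)
    mid = slice(ph.n_samples // 4, 3 * ph.n_samples // 4)
    dphi = np.angle(np.exp(1j * (ph.phase[0, mid] - ph.phase[1, mid])))
    assert np.allclose(dphi, np.pi / 2, atol=0.01)


def test_short_series_rejected(make_series):
    s = _sine_series(make_series, np.zeros((2, 100)), 2.0)
    with pytest.raises(InvalidArgumentError):
        instantaneous_phase(s, edge_trim_s=30.0)


def test_unfiltered_series_warns(make_series):
    s = make_series(np.random.default_rng(0).normal(size=(2, 400)), band=None)
    with pytest.warns(UserWarning, match="pass band"):
        instantaneous_phase(s, edge_trim_s=10.0)


def test_plv_identity_and_cancellation():
    a = np.linspace(-np.pi, np.pi, 500)
    assert plv(a, a) == 1.0
    b = np.zeros(500)
    alt = np.tile([0.0, np.pi], 250)
    assert plv(alt, b) < 1e-12
    quad = np.tile([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], 25)
    assert plv(quad, np.zeros_like(quad)) < 1e-12
    with pytest.raises(InvalidArgumentError):
        plv(a, a[:-1])


def test_plv_global_phase_offset_invariance():
    rng = np.random.default_rng(0)
    a, b = rng.uniform(-np.pi, np.pi, (2, 1000))
    assert plv(a + 1.234, b) == pytest.approx(plv(a, b), abs=1e-12)
    assert plv(a, b) == pytest.approx(plv(b, a), abs=0)


def test_plv_uniform_phase_monte_carlo():
    """Null PLV of N iid uniform phases matches E[R] = sqrt(pi)/(2 sqrt(N))."""
    rng = np.random.default_rng(42)
    N, reps = 1000, 1000
    dphi = rng.uniform(-np.pi, np.pi, size=(reps, N))
    r = np.abs(np.exp(1j * dphi).mean(axis=1))
    expected = np.sqrt(np.pi) / (2 * np.sqrt(N))
    se = r.std(ddof=1) / np.sqrt(reps)
    assert abs(r.mean() - expected) < 3 * se


def test_plv_matrix_symmetry_diagonal_and_coupling(schedule, layout):
    s = simulate_hemodynamics(
        schedule,
        layout,
        coupling=CouplingSpec(pairs=(("Ch01", "Ch02"),), strength=1.0),
        noise=NoiseSpec(cardiac_uM=0, respiratory_uM=0, mayer_uM=0,
                        white_sd_uM=0, drift_slope_uM_per_s=0, band_sd_uM=0.1),
        response=ResponseSpec(amplitude_uM=0.0),
        seed=0,
    )
    f = preprocess(s, schedule)
    m = plv_matrix(f, schedule.condition_segment(schedule.condition_order[0]))
    assert np.max(np.abs(m.values - m.values.T)) == 0.0
    assert np.all(np.diag(m.values) == 1.0)
    assert m.loc("Ch01", "Ch02") >= 0.99


def test_independent_channels_low_plv(schedule, layout):
    s = simulate_hemodynamics(
        schedule, layout, response=ResponseSpec(amplitude_uM=0.0), seed=5
    )
    f = preprocess(s, schedule)
    m = plv_matrix(f, schedule.condition_segment(schedule.condition_order[0]))
    off = m.values[~np.eye(15, dtype=bool)]
    assert np.median(off) < 0.5


def test_segment_too_short_rejected(schedule, layout):
    s = simulate_hemodynamics(schedule, layout, seed=0)
    f = preprocess(s, schedule)
    with pytest.raises(SegmentLengthError):
        plv_matrix(f, (0.0, 300.0))


def test_coupling_strength_monotonically_increases_plv(schedule, layout):
    """Mean planted-pair PLV rises strictly along a 5-point strength grid
    (Spearman rho = 1 on seeded replicates)."""
    from scipy.stats import spearmanr

    strengths = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = []
    pairs = (("Ch01", "Ch02"), ("Ch05", "Ch09"), ("Ch10", "Ch13"))
    idx = [(0, 1), (4, 8), (9, 12)]
    for k, s0 in enumerate(strengths):
        vals = []
        for r in range(3):
            s = simulate_hemodynamics(
                schedule, layout,
                coupling=CouplingSpec(pairs=pairs, strength=s0),
                response=ResponseSpec(amplitude_uM=0.0),
                seed=300 + r,
            )
            f = preprocess(s, schedule)
            m = plv_matrix(f, schedule.condition_segment(schedule.condition_order[0]))
            vals.append(np.mean([m.values[i, j] for i, j in idx]))
        means.append(np.mean(vals))
    assert np.all(np.diff(means) > 0)
    rho, _ = spearmanr(strengths, means)
    assert rho == pytest.approx(1.0)


def test_roi_mean_connectivity(roi_map, layout):
    ones = ConnectivityMatrix(np.ones((15, 15)), layout.channels)
    agg = roi_mean_connectivity(ones, roi_map)
    assert np.allclose(agg.values, 1.0)

    rng = np.random.default_rng(0)
    v = rng.uniform(0.1, 0.9, size=(15, 15))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    m = ConnectivityMatrix(v, layout.channels)
    # hand mean of the two ROI1-ROI4 channel pairs
    m.values[0, 7] = m.values[7, 0] = 0.4
    m.values[1, 7] = m.values[7, 1] = 0.6
    agg = roi_mean_connectivity(m, roi_map)
    assert agg.loc("ROI1", "ROI4") == pytest.approx(0.5)
    # every ROI entry bounded by its constituent channel entries
    for i, a in enumerate(agg.labels):
        for j, b in enumerate(agg.labels):
            if i >= j:
                continue
            ia = [layout.index(c) for c in roi_map.rois[a]]
            ib = [layout.index(c) for c in roi_map.rois[b]]
            block = m.values[np.ix_(ia, ib)]
            assert block.min() - 1e-12 <= agg.values[i, j] <= block.max() + 1e-12


def test_seed_profile_ordering():
    labels = tuple(f"ROI{i}" for i in range(1, 8))
    v = np.ones((7, 7))
    row = [0.1, 0.2, 0.3, 1.0, 0.5, 0.6, 0.7]
    v[3, :] = row
    v[:, 3] = row
    prof = seed_profile(ConnectivityMatrix(v, labels))
    assert list(prof.index) == ["S1", "S2", "S3", "S4", "S5", "S6"]
    assert list(prof) == [0.1, 0.2, 0.3, 0.5, 0.6, 0.7]
    all_ones = seed_profile(ConnectivityMatrix(np.ones((7, 7)), labels))
    assert (all_ones == 1.0).all()


def test_binarize_strict_threshold():
    labels = ("a", "b", "c")
    v = np.array([[1.0, 0.69, 0.70], [0.69, 1.0, 0.71], [0.70, 0.71, 1.0]])
    edges = binarize(ConnectivityMatrix(v, labels), 0.7)
    assert len(edges) == 1
    assert tuple(edges.iloc[0]) == ("b", "c")
    assert len(binarize(ConnectivityMatrix(v, labels), 1.0)) == 0
    assert len(binarize(ConnectivityMatrix(v, labels), 0.0)) == 3
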