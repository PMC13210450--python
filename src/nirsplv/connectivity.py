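"""Phase-locking-value connectivity.

The PLV between two signals is the modulus of the time-averaged unit
phasor of their instantaneous phase difference,

    PLV = | (1/N) Σ_t exp(j Δϕ_t) | ∈ [0, 1],

with instantaneous phases taken as the angle of the analytic signal
(Hilbert transform) of the band-limited (0.005–0.05 Hz) record. PLV is
estimated over the continuous ~10 min segment of each condition block
(never over concatenated pieces — phase continuity requires unbroken
time), with a configurable edge trim (default 50 s per end) to discard
Hilbert end transients. An optional trial-wise mode computes phase
consistency at each latency across trial epochs instead.

Channel-level 15×15 matrices are averaged into a 7×7 ROI matrix (mean
PLV over all channel pairs linking two ROIs); the seed profile S1..S6
is the seed ROI's row against the six target ROIs. Binarization at a
PLV threshold (strictly greater than, default 0.7) is for
visualization only and never feeds graph metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .containers import EpochSet, HemoSeries
from .errors import InvalidArgumentError, SegmentLengthError
from .layout import ROIMap, SEED_LABELS, SEED_ROI, SEED_TARGETS

logger = logging.getLogger(__name__)

DEFAULT_EDGE_TRIM_S = 50.0
DEFAULT_MIN_SEGMENT_S = 400.0
DEFAULT_BINARY_THRESHOLD = 0.7


@dataclass
class PhaseSeries:
    """Instantaneous phase per channel, wrapped to (−π, π]."""

    phase: np.ndarray  # (channels, samples)
    rate_hz: float
    band_hz: tuple[float, float] | None = None

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]


@dataclass
class ConnectivityMatrix:
    """Symmetric PLV matrix with node labels (channels or ROIs)."""

    values: np.ndarray
    labels: tuple[str, ...]
    diagonal: str = "self"  # self-PLV convention: diagonal = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidArgumentError("matrix shape must match label count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def instantaneous_phase(
    series: HemoSeries, edge_trim_s: float = DEFAULT_EDGE_TRIM_S
) -> PhaseSeries:
    """Analytic-signal angle per sample, edges trimmed on both ends.

    The caller is expected to band-pass filter first; a series without
    a recorded pass band is accepted but triggers a warning.
    """
    if series.band_hz is None:
        warnings.warn(
            "instantaneous_phase called on a series with no recorded pass band; "
            "phases of broadband signals are not interpretable",
            stacklevel=2,
        )
    n_trim = int(round(edge_trim_s * series.rate_hz))
    if series.n_samples <= 2 * n_trim:
        raise InvalidArgumentError(
            f"series of {series.n_samples} samples is too short for an edge trim "
            f"of {edge_trim_s} s per end"
        )
    phase = np.angle(hilbert(series.hbo, axis=-1))
    if n_trim:
        phase = phase[:, n_trim:-n_trim]
    return PhaseSeries(phase=phase, rate_hz=series.rate_hz, band_hz=series.band_hz)


def plv(phase_a: np.ndarray | PhaseSeries, phase_b: np.ndarray | PhaseSeries) -> float:
    """PLV of two equal-length phase series."""
    a = phase_a.phase if isinstance(phase_a, PhaseSeries) else np.asarray(phase_a, float)
    b = phase_b.phase if isinstance(phase_b, PhaseSeries) else np.asarray(phase_b, float)
    a, b = a.ravel(), b.ravel()
    if a.shape != b.shape:
        raise InvalidArgumentError("phase series lengths differ")
    if a.size < 2:
        raise InvalidArgumentError("PLV requires at least 2 samples")
    return float(np.abs(np.exp(1j * (a - b)).mean()))


def plv_matrix_from_phase(phase: np.ndarray, labels: tuple[str, ...]) -> ConnectivityMatrix:
    """All-pairs PLV from a (channels, samples) phase array."""
    z = np.exp(1j * phase)
    m = np.abs(z @ z.conj().T) / phase.shape[-1]
    m = 0.5 * (m + m.T)  # enforce exact symmetry against rounding
    np.fill_diagonal(m, 1.0)
    return ConnectivityMatrix(values=np.clip(m, 0.0, 1.0), labels=labels)


def plv_matrix(
    series: HemoSeries,
    segment_s: tuple[float, float] | None = None,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
    min_segment_s: float = DEFAULT_MIN_SEGMENT_S,
) -> ConnectivityMatrix:
    """Channel×channel PLV over one continuous segment.

    ``segment_s`` is a (start, stop) window in seconds (e.g. one
    condition block); ``None`` uses the whole record. Segments shorter
    than ``min_segment_s`` (default two cycles of the lowest band
    frequency) are rejected.
    """
    if segment_s is not None:
        t0, t1 = segment_s
        if not 0 <= t0 < t1 <= series.duration_s + 1e-9:
            raise InvalidArgumentError(f"segment {segment_s} outside record span")
        i0, i1 = int(round(t0 * series.rate_hz)), int(round(t1 * series.rate_hz))
        sub = series.copy_with(hbo=series.hbo[:, i0:i1], hbr=None, markers=None)
    else:
        sub = series
    if sub.duration_s < min_segment_s:
        raise SegmentLengthError(
            f"segment of {sub.duration_s:.1f} s is shorter than the "
            f"{min_segment_s:.0f} s minimum for stable phase estimation"
        )
    ph = instantaneous_phase(sub, edge_trim_s)
    return plv_matrix_from_phase(ph.phase, series.layout.channels)


def plv_matrix_trialwise(epochs: EpochSet, condition: str | None = None) -> ConnectivityMatrix:
    """Trial-wise PLV variant: phase-difference consistency across trials,
    averaged over epoch latencies. Offered for comparability only; the
    primary definition is the continuous-segment PLV."""
    sel = epochs if condition is None else epochs.select(condition=condition)
    if sel.n_epochs < 2:
        raise InvalidArgumentError("trial-wise PLV needs at least 2 epochs")
    phase = np.angle(hilbert(sel.data, axis=-1))  # (trials, ch, t)
    z = np.exp(1j * phase)
    # consistency across trials at each latency, then mean over latencies
    m = np.abs(np.einsum("kct,kdt->cdt", z, z.conj()) / sel.n_epochs).mean(axis=-1)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return ConnectivityMatrix(np.clip(m, 0.0, 1.0), sel.layout.channels)


def roi_mean_connectivity(matrix: ConnectivityMatrix, roi_map: ROIMap) -> ConnectivityMatrix:
    """Average channel-level PLV into an ROI×ROI matrix.

    Off-diagonal (A, B): mean over all channel pairs (a ∈ A, b ∈ B).
    Diagonal (A, A): mean over within-ROI pairs, or 1 for a singleton
    ROI (the self-PLV convention; diagonals never enter statistics).
    """
    labels = list(matrix.labels)
    idx = {roi: [labels.index(ch) for ch in chans] for roi, chans in roi_map.rois.items()}
    rois = list(roi_map.rois)
    n = len(rois)
    out = np.ones((n, n))
    for i, a in enumerate(rois):
        ia = idx[a]
        for j, b in enumerate(rois):
            if i < j:
                block = matrix.values[np.ix_(ia, idx[b])]
                out[i, j] = out[j, i] = block.mean()
            elif i == j and len(ia) > 1:
                iu, ju = np.triu_indices(len(ia), k=1)
                out[i, i] = matrix.values[np.ix_(ia, ia)][iu, ju].mean()
    return ConnectivityMatrix(values=out, labels=tuple(rois))


def seed_profile(roi_matrix: ConnectivityMatrix, seed: str = SEED_ROI) -> pd.Series:
    """Seed-based profile S1..S6: seed-ROI row against the target ROIs."""
    targets = [r for r in roi_matrix.labels if r != seed]
    if seed not in roi_matrix.labels:
        raise InvalidArgumentError(f"seed {seed!r} not among ROI labels")
    if tuple(roi_matrix.labels) == ("ROI1", "ROI2", "ROI3", "ROI4", "ROI5", "ROI6", "ROI7"):
        targets = list(SEED_TARGETS)
        names = list(SEED_LABELS)
    else:
        names = [f"S{i+1}" for i in range(len(targets))]
    values = [roi_matrix.loc(seed, t) for t in targets]
    return pd.Series(values, index=pd.Index(names, name="connection"), name=seed)


def binarize(
    matrix: ConnectivityMatrix, threshold: float = DEFAULT_BINARY_THRESHOLD
) -> pd.DataFrame:
    """Edge list of node pairs with PLV strictly exceeding ``threshold``.

    Visualization aid only — graph metrics always use the full
    weighted matrix.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidArgumentError("threshold must lie in [0, 1]")
    rows = []
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] > threshold:
                rows.append({"node_a": matrix.labels[i], "node_b": matrix.labels[j]})
    return pd.DataFrame(rows, columns=["node_a", "node_b"])


def condition_matrices(
    filtered: HemoSeries,
    schedule,
    roi_map: ROIMap | None = None,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
    min_segment_s: float = DEFAULT_MIN_SEGMENT_S,
) -> dict[str, dict[str, object]]:
    """Per-condition channel and ROI matrices plus the seed profile."""
    out: dict[str, dict[str, object]] = {}
    for cond in schedule.condition_order:
        seg = schedule.condition_segment(cond)
        chan = plv_matrix(filtered, seg, edge_trim_s, min_segment_s)
        entry: dict[str, object] = {"channel": chan}
        if roi_map is not None:
            roi = roi_mean_connectivity(chan, roi_map)
            entry["roi"] = roi
            entry["seed"] = seed_profile(roi)
        out[cond] = entry
    return out
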