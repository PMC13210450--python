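"""Synthetic fNIRS generator: ground-truth hemodynamics with planted
phase coupling, physiological noise, and behavioral selection logs.

The generator emulates the block-design study: per condition, 10 trials
of 0.5 s introduction + 24 s task (three 8 s selection screens) + 35 s
rest, recorded over 15 prefrontal channels at 8.138 Hz. Each channel's
ΔHbO is

    response + band-limited background + physiological noise,

where the response is a canonical double-gamma HRF convolved with the
task boxcar (condition-dependent amplitude per channel), the background
is a unit-variance 0.005–0.05 Hz process that optionally shares a
common narrowband oscillator across designated channel pairs (the
planted phase coupling that connectivity analyses must recover), and
the noise comprises cardiac (~1 Hz), respiratory (~0.3 Hz) and Mayer
(~0.1 Hz) sinusoids, white noise, slow drift and optional motion
spikes. ΔHbR is emitted as a scaled, sign-inverted companion of ΔHbO
plus independent noise; the analysis chain uses ΔHbO only.

All routines are deterministic given (spec, seed). Internals carry a
leading subject axis so group-level Monte-Carlo studies can be
generated in one vectorized pass; the public single-record API wraps a
batch of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import NOMINAL_RATE_HZ, HemoSeries
from .errors import InvalidArgumentError
from .layout import ChannelLayout, default_layout
from .paradigm import CONDITIONS, ParadigmSchedule

BAND_HZ = (0.005, 0.05)


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response function.

    peak_s / undershoot_s are the modes of the positive and negative
    gamma lobes; ratio is the undershoot amplitude relative to the
    peak. Defaults are the conventional 6 s / 16 s / 1:6 shape.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model (amplitudes in μM, frequencies in Hz)."""

    cardiac_hz: float = 1.0
    cardiac_uM: float = 0.2
    respiratory_hz: float = 0.3
    respiratory_uM: float = 0.1
    mayer_hz: float = 0.1
    mayer_uM: float = 0.1
    white_sd_uM: float = 0.05
    drift_slope_uM_per_s: float = 0.001
    band_sd_uM: float = 0.3
    motion_rate_hz: float = 0.0
    motion_uM: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "cardiac_uM", "respiratory_uM", "mayer_uM",
            "white_sd_uM", "band_sd_uM", "motion_rate_hz", "motion_uM",
        ):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        for name in ("cardiac_hz", "respiratory_hz", "mayer_hz"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Planted phase coupling among designated channel pairs.

    Every channel appearing in ``pairs`` mixes a shared narrowband
    oscillator at ``frequency_hz`` into its band-limited background:
    fraction ``strength`` of the band variance comes from the shared
    oscillator (strength 1 → identical phases up to the fixed per-channel
    lag → downstream PLV of a designated pair → 1).
    """

    pairs: tuple[tuple[str, str], ...] = ()
    frequency_hz: float = 0.02
    strength: float = 0.0
    phase_lag_rad: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise InvalidArgumentError("coupling strength must lie in [0, 1]")

    def channels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a, b in self.pairs:
            for ch in (a, b):
                if ch not in seen:
                    seen.append(ch)
        return tuple(seen)

    def validate(self, layout: ChannelLayout, rate_hz: float) -> None:
        for ch in self.channels():
            layout.index(ch)  # raises LayoutError for unknown channels
        if not 0.0 < self.frequency_hz < rate_hz / 2:
            raise InvalidArgumentError(
                f"coupling frequency {self.frequency_hz} Hz outside (0, Nyquist)"
            )


@dataclass(frozen=True)
class ResponseSpec:
    """Task-evoked response amplitudes (μM) per condition.

    ``amplitude_uM`` maps condition → scalar or per-channel array; a
    bare scalar applies to both conditions and all channels.
    """

    amplitude_uM: float | dict[str, np.ndarray | float] = 0.3

    def per_channel(self, condition: str, n_channels: int) -> np.ndarray:
        amp = self.amplitude_uM
        if isinstance(amp, dict):
            amp = amp.get(condition, 0.0)
        return np.broadcast_to(np.asarray(amp, dtype=float), (n_channels,)).copy()


@dataclass(frozen=True)
class BehaviorEffectSpec:
    """Behavioral generative model for the selection log.

    RT means/sds are per-selection response times (ms, truncated to the
    8 s screen); low-price probabilities give the chance of picking one
    of the two lower-priced (non-packed) options on a screen.
    """

    rt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {"OOC": 3650.0, "SOC": 3500.0}
    )
    rt_sd_ms: dict[str, float] = field(
        default_factory=lambda: {"OOC": 900.0, "SOC": 900.0}
    )
    low_price_prob: dict[str, float] = field(
        default_factory=lambda: {"OOC": 7.0 / 30.0, "SOC": 23.0 / 30.0}
    )

    def __post_init__(self) -> None:
        for c, p in self.low_price_prob.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError(f"low_price_prob[{c}] must lie in [0, 1]")
        for c, s in self.rt_sd_ms.items():
            if s <= 0:
                raise InvalidArgumentError(f"rt_sd_ms[{c}] must be > 0")


# --------------------------------------------------------------------------
# hemodynamic response


def double_gamma_hrf(rate_hz: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sampled canonical HRF, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, params.duration_s, 1.0 / rate_hz)
    # shape a, scale 1 gamma density peaks at (a-1): choose a = peak + 1
    peak = gamma_dist.pdf(t, params.peak_s + 1.0)
    under = gamma_dist.pdf(t, params.undershoot_s + 1.0)
    h = peak - params.ratio * under
    return h / h.max()


def _band_sos(rate_hz: float) -> np.ndarray:
    return sps.butter(3, BAND_HZ, btype="band", fs=rate_hz, output="sos")


def _boxcar(schedule: ParadigmSchedule, condition: str, n: int, rate_hz: float) -> np.ndarray:
    box = np.zeros(n)
    for onset in schedule.task_onsets(condition):
        i0 = int(np.round(onset * rate_hz))
        i1 = min(n, int(np.round((onset + schedule.task_s) * rate_hz)))
        box[i0:i1] = 1.0
    return box


# --------------------------------------------------------------------------
# batch core


def synthesize_hbo_batch(
    schedules: list[ParadigmSchedule],
    layout: ChannelLayout,
    coupling: list[dict[str, CouplingSpec]],
    noise: NoiseSpec,
    response_amps: np.ndarray,
    hrf_params: HRFParams,
    rng: np.random.Generator,
    rate_hz: float = NOMINAL_RATE_HZ,
    dtype: np.dtype | type = np.float64,
) -> np.ndarray:
    """Generate ΔHbO for a batch of subjects; returns (S, C, T) in μM.

    ``schedules`` gives one schedule per subject (same durations, block
    order may differ). ``coupling[s]`` maps condition → CouplingSpec
    active inside that condition's segment. ``response_amps`` is
    (S, n_conditions, C) ordered like :data:`CONDITIONS`.
    """
    n_sub = len(schedules)
    n_ch = layout.n_channels
    n = int(np.round(schedules[0].session_span_s * rate_hz))
    dtype = np.dtype(dtype)
    t = (np.arange(n) / rate_hz).astype(dtype)

    for cmap in coupling:
        for spec in cmap.values():
            spec.validate(layout, rate_hz)

    # --- task-evoked response: one boxcar template per (order, condition)
    h = double_gamma_hrf(rate_hz, hrf_params)
    conv_cache: dict[tuple[str, str], np.ndarray] = {}
    for sched in schedules:
        key0 = sched.condition_order[0]
        for cond in CONDITIONS:
            if (key0, cond) not in conv_cache:
                box = _boxcar(sched, cond, n, rate_hz)
                conv = sps.fftconvolve(box, h)[:n]
                peak = np.abs(conv).max()
                if peak > 0:
                    conv = conv / peak  # amplitude_uM = peak evoked ΔHbO
                conv_cache[(key0, cond)] = conv.astype(dtype)
    x = np.zeros((n_sub, n_ch, n), dtype=dtype)
    for s, sched in enumerate(schedules):
        for ci, cond in enumerate(CONDITIONS):
            x[s] += response_amps[s, ci][:, None] * conv_cache[(sched.condition_order[0], cond)]

    # --- band-limited background with optional shared oscillators.
    # Synthesized spectrally: Gaussian spectrum shaped by the band-pass
    # magnitude response is the stationary equivalent of filtering white
    # noise, and each channel is renormalized to unit variance anyway.
    if noise.band_sd_uM > 0:
        freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
        _, H = sps.sosfreqz(_band_sos(rate_hz), worN=2 * np.pi * freqs / rate_hz)
        mag = np.abs(H).astype(dtype)
        spec = mag * (
            rng.standard_normal((n_sub, n_ch, mag.size), dtype=dtype)
            + 1j * rng.standard_normal((n_sub, n_ch, mag.size), dtype=dtype)
        )
        intrinsic = np.fft.irfft(spec, n=n, axis=-1).astype(dtype, copy=False)
        intrinsic /= intrinsic.std(axis=-1, keepdims=True)
        band = noise.band_sd_uM * intrinsic
        for s, cmap in enumerate(coupling):
            for cond, spec_ in cmap.items():
                if spec_.strength == 0 or not spec_.pairs:
                    continue
                t0, t1 = schedules[s].condition_segment(cond)
                i0, i1 = int(round(t0 * rate_hz)), min(n, int(round(t1 * rate_hz)))
                phi0 = rng.uniform(0, 2 * np.pi)
                for ch in spec_.channels():
                    k = layout.index(ch)
                    lag = spec_.phase_lag_rad.get(ch, 0.0)
                    osc = np.sqrt(2.0) * np.sin(
                        2 * np.pi * spec_.frequency_hz * t[i0:i1] + phi0 + lag
                    )
                    band[s, k, i0:i1] = noise.band_sd_uM * (
                        np.sqrt(spec_.strength) * osc
                        + np.sqrt(1.0 - spec_.strength) * intrinsic[s, k, i0:i1]
                    )
        x += band

    # --- physiological sinusoids, white noise, drift, motion
    for amp, f in (
        (noise.cardiac_uM, noise.cardiac_hz),
        (noise.respiratory_uM, noise.respiratory_hz),
        (noise.mayer_uM, noise.mayer_hz),
    ):
        if amp > 0:
            phases = rng.uniform(0, 2 * np.pi, size=(n_sub, n_ch, 1))
            # amp·sin(ωt + φ) expanded so sin/cos run over t only
            st, ct = np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)
            x += (amp * np.cos(phases)) * st
            x += (amp * np.sin(phases)) * ct
    if noise.white_sd_uM > 0:
        x += noise.white_sd_uM * rng.standard_normal((n_sub, n_ch, n), dtype=dtype)
    if noise.drift_slope_uM_per_s != 0:
        x += noise.drift_slope_uM_per_s * (t - t.mean())
    if noise.motion_rate_hz > 0 and noise.motion_uM > 0:
        n_spikes = rng.poisson(noise.motion_rate_hz * t[-1], size=(n_sub, n_ch))
        decay = np.exp(-np.arange(int(rate_hz)) / (0.3 * rate_hz))
        for s in range(n_sub):
            for c in range(n_ch):
                for t0 in rng.uniform(0, t[-1], size=n_spikes[s, c]):
                    i0 = int(t0 * rate_hz)
                    seg = decay[: n - i0]
                    x[s, c, i0 : i0 + len(seg)] += (
                        noise.motion_uM * rng.choice([-1.0, 1.0]) * seg
                    )
    return x


# --------------------------------------------------------------------------
# public single-record API


def simulate_hemodynamics(
    schedule: ParadigmSchedule,
    layout: ChannelLayout | None = None,
    coupling: CouplingSpec | dict[str, CouplingSpec] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    response: ResponseSpec = ResponseSpec(),
    hrf_params: HRFParams = HRFParams(),
    seed: int | np.random.Generator = 0,
    rate_hz: float = NOMINAL_RATE_HZ,
) -> HemoSeries:
    """Ground-truth ΔHbO/ΔHbR series for one recording session.

    ``coupling`` may be a single spec (active in both condition
    segments) or a condition → spec mapping. Identical (spec, seed)
    yields bit-identical output.
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    if coupling is None:
        cmap: dict[str, CouplingSpec] = {}
    elif isinstance(coupling, CouplingSpec):
        cmap = {cond: coupling for cond in CONDITIONS}
    else:
        cmap = dict(coupling)
    amps = np.stack(
        [response.per_channel(cond, layout.n_channels) for cond in CONDITIONS]
    )[None, :, :]
    hbo = synthesize_hbo_batch(
        [schedule], layout, [cmap], noise, amps, hrf_params, rng, rate_hz
    )[0]
    hbr = -(1.0 / 3.0) * hbo
    if noise.white_sd_uM > 0:
        hbr = hbr + noise.white_sd_uM * rng.standard_normal(hbo.shape)
    return HemoSeries(
        hbo=hbo,
        hbr=hbr,
        rate_hz=rate_hz,
        layout=layout,
        markers=schedule.events.copy(),
        meta={"seed": None if isinstance(seed, np.random.Generator) else int(seed)},
    )


# --------------------------------------------------------------------------
# behavior


def simulate_behavior(
    schedule: ParadigmSchedule,
    effects: BehaviorEffectSpec = BehaviorEffectSpec(),
    seed: int | np.random.Generator = 0,
    subject: int = 1,
) -> pd.DataFrame:
    """Selection log: one row per stimulus screen (selection event).

    Columns: subject, condition, trial, screen, rt_ms, chosen_option,
    price_tier, packaging. RTs are truncated to (0, 8000] ms. Each
    screen offers four options — two lower-priced non-packed and two
    higher-priced packed; the low-price choice probability is
    condition-dependent.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ev in schedule.events.itertuples(index=False):
        p_low = effects.low_price_prob[ev.condition]
        low = rng.random() < p_low
        rt = rng.normal(effects.rt_mean_ms[ev.condition], effects.rt_sd_ms[ev.condition])
        rt = float(np.clip(rt, 1.0, schedule.screen_s * 1000.0))
        option = int(rng.integers(2)) + (0 if low else 2)
        rows.append(
            {
                "subject": subject,
                "condition": ev.condition,
                "trial": ev.trial,
                "screen": ev.screen_index,
                "rt_ms": rt,
                "chosen_option": ["h", "j", "k", "l"][option],
                "price_tier": "low" if low else "high",
                "packaging": "none" if low else "packed",
            }
        )
    return pd.DataFrame(rows)
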