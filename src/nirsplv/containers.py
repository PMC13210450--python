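"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError, LayoutError
from .layout import ChannelLayout

NOMINAL_RATE_HZ = 8.138


def _check_markers(markers: pd.DataFrame | None, duration: float) -> pd.DataFrame:
    if markers is None:
        return pd.DataFrame(columns=["onset_s", "duration_s", "condition", "screen_index"])
    if len(markers) and (
        (markers["onset_s"] < 0).any() or (markers["onset_s"] > duration).any()
    ):
        raise DataError("marker times fall outside the recording span")
    return markers.reset_index(drop=True)


@dataclass
class RawIntensitySeries:
    """Dual-wavelength optical intensity per channel.

    ``data`` has shape (n_channels, n_wavelengths, n_samples); intensity
    is strictly positive. ``baseline`` holds the per-channel/wavelength
    reference intensity used for optical-density changes.
    """

    data: np.ndarray
    rate_hz: float
    layout: ChannelLayout
    baseline: np.ndarray | None = None
    markers: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError(
                "intensity data must be (channels, wavelengths, samples)"
            )
        if self.rate_hz <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if self.data.shape[0] != self.layout.n_channels:
            raise LayoutError(
                f"{self.data.shape[0]} channels in data, "
                f"{self.layout.n_channels} in layout"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data <= 0):
            bad = np.argwhere(~(np.isfinite(self.data) & (self.data > 0)))[0]
            raise DataError(
                f"non-positive or non-finite intensity at channel index {bad[0]}, "
                f"wavelength index {bad[1]}, sample {bad[2]}"
            )
        if self.baseline is None:
            self.baseline = self.data.mean(axis=2)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.markers = _check_markers(self.markers, self.duration_s)

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.data.shape[2] / self.rate_hz


@dataclass
class HemoSeries:
    """Multichannel hemoglobin-concentration change time series (μM).

    ``hbo`` (and optional ``hbr``) have shape (n_channels, n_samples).
    ``band_hz`` records the pass band once the series has been
    band-pass filtered; phase estimation checks it.
    """

    hbo: np.ndarray
    rate_hz: float
    layout: ChannelLayout
    hbr: np.ndarray | None = None
    markers: pd.DataFrame | None = None
    band_hz: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        if self.rate_hz <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if self.hbo.shape[0] != self.layout.n_channels:
            raise LayoutError(
                f"{self.hbo.shape[0]} channels in data, "
                f"{self.layout.n_channels} in layout"
            )
        if not np.all(np.isfinite(self.hbo)):
            raise DataError("non-finite ΔHbO values")
        if self.hbr is not None:
            self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
            if self.hbr.shape != self.hbo.shape:
                raise InvalidArgumentError("ΔHbR shape must match ΔHbO")
        self.markers = _check_markers(self.markers, self.duration_s)

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def copy_with(self, **kwargs) -> "HemoSeries":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.hbo.T, columns=list(self.layout.channels))
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class EpochSet:
    """Trial-locked epochs: (n_epochs, n_channels, n_times) ΔHbO array.

    ``index`` carries one row per epoch (subject, condition, trial);
    ``times`` is the common epoch time axis relative to task onset.
    """

    data: np.ndarray
    index: pd.DataFrame
    times: np.ndarray
    rate_hz: float
    layout: ChannelLayout
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    dropped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("epochs must be (epochs, channels, times)")
        if len(self.index) != self.data.shape[0]:
            raise InvalidArgumentError("index length must match epoch count")
        if self.data.shape[2] != len(self.times):
            raise InvalidArgumentError("time axis length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, **query) -> "EpochSet":
        mask = np.ones(self.n_epochs, dtype=bool)
        for key, value in query.items():
            mask &= (self.index[key] == value).to_numpy()
        return EpochSet(
            data=self.data[mask],
            index=self.index[mask].reset_index(drop=True),
            times=self.times,
            rate_hz=self.rate_hz,
            layout=self.layout,
            baseline_window_s=self.baseline_window_s,
        )
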