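"""Probe geometry and region-of-interest parcellation.

The wearable probe covers the prefrontal cortex with 15 channels
(source-detector pairs at 3 cm separation, two near-infrared
wavelengths). For regional analyses the channels are grouped into seven
functional ROIs; ROI4 (the single central channel, adjacent to the
medial PFC) serves as the seed of the seed-based connectivity profile
S1..S6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError, LayoutError

N_CHANNELS = 15
CHANNEL_IDS = tuple(f"Ch{i:02d}" for i in range(1, N_CHANNELS + 1))

#: ROI -> channel labels (a partition of the 15 channels).
DEFAULT_ROI_CHANNELS: dict[str, tuple[str, ...]] = {
    "ROI1": ("Ch01", "Ch02"),
    "ROI2": ("Ch03", "Ch05", "Ch06"),
    "ROI3": ("Ch04", "Ch07"),
    "ROI4": ("Ch08",),
    "ROI5": ("Ch09", "Ch11", "Ch12"),
    "ROI6": ("Ch10", "Ch13"),
    "ROI7": ("Ch14", "Ch15"),
}

#: Anatomical region name per ROI.
ROI_REGIONS: dict[str, str] = {
    "ROI1": "Lateral right",
    "ROI2": "Upper right",
    "ROI3": "Lower right",
    "ROI4": "Center",
    "ROI5": "Upper left",
    "ROI6": "Lower left",
    "ROI7": "Lateral left",
}

SEED_ROI = "ROI4"
#: Target ordering of the seed-based connections S1..S6.
SEED_TARGETS = ("ROI1", "ROI2", "ROI3", "ROI5", "ROI6", "ROI7")
SEED_LABELS = tuple(f"S{i}" for i in range(1, 7))


@dataclass(frozen=True)
class ChannelLayout:
    """Probe layout: channel ids, optode pairing, geometry and optics.

    Parameters
    ----------
    channels : tuple of str
        Channel labels, ``Ch01`` .. ``Ch15`` by default.
    source_detector : tuple of (int, int)
        Source and detector index per channel (1-based).
    distance_cm : float
        Inter-optode distance; 3 cm for this probe.
    wavelengths_nm : tuple of float
        Nominal wavelength pair of the device.
    """

    channels: tuple[str, ...] = CHANNEL_IDS
    source_detector: tuple[tuple[int, int], ...] = tuple(
        (i, i) for i in range(1, N_CHANNELS + 1)
    )
    distance_cm: float = 3.0
    wavelengths_nm: tuple[float, float] = (780.0, 850.0)

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.source_detector):
            raise LayoutError("one source-detector pair is required per channel")
        if self.distance_cm <= 0:
            raise InvalidArgumentError("inter-optode distance must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise LayoutError(f"unknown channel {channel!r}") from None


@dataclass(frozen=True)
class ROIMap:
    """Partition of the channels into named regions of interest."""

    rois: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_CHANNELS)
    )
    regions: dict[str, str] = field(default_factory=lambda: dict(ROI_REGIONS))

    def validate(self, layout: ChannelLayout) -> None:
        """Check the map is a disjoint, exhaustive partition of the layout."""
        seen: list[str] = []
        for roi, chans in self.rois.items():
            for ch in chans:
                if ch not in layout.channels:
                    raise LayoutError(f"{roi} references unknown channel {ch!r}")
                if ch in seen:
                    raise LayoutError(f"channel {ch!r} assigned to more than one ROI")
                seen.append(ch)
        missing = set(layout.channels) - set(seen)
        if missing:
            raise LayoutError(f"channels not assigned to any ROI: {sorted(missing)}")

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(self.rois)

    def channel_indices(self, layout: ChannelLayout) -> dict[str, list[int]]:
        return {
            roi: [layout.index(ch) for ch in chans]
            for roi, chans in self.rois.items()
        }


def default_layout() -> ChannelLayout:
    return ChannelLayout()


def default_roi_map() -> ROIMap:
    return ROIMap()
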