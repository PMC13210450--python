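import numpy as np
import pytest

from nirsplv import default_layout, default_roi_map, generate_paradigm
from nirsplv.containers import HemoSeries
from nirsplv.layout import ChannelLayout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def roi_map():
    return default_roi_map()


@pytest.fixture(scope="session")
def schedule():
    return generate_paradigm(10, order_seed=0)


@pytest.fixture(scope="session")
def two_channel_layout():
    return ChannelLayout(channels=("A", "B"), source_detector=((1, 1), (2, 2)))


@pytest.fixture
def make_series(two_channel_layout):
    """Factory: wrap per-channel arrays into a HemoSeries on a small probe."""

    def _make(rows, rate_hz=2.0, band=(0.005, 0.05), layout=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        lay = layout
        if lay is None:
            if rows.shape[0] == 2:
                lay = two_channel_layout
            else:
                lay = ChannelLayout(
                    channels=tuple(f"C{i}" for i in range(rows.shape[0])),
                    source_detector=tuple((i + 1, i + 1) for i in range(rows.shape[0])),
                )
        return HemoSeries(hbo=rows, rate_hz=rate_hz, layout=lay, band_hz=band)

    return _make
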