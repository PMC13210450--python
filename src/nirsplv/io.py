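"""Reading and writing recordings, events, logs and matrices.

Two on-disk forms are supported for recordings:

* SNIRF (HDF5, v1.0 layout) for raw dual-wavelength intensities, with
  stimulus blocks per condition mapped to/from the events table;
* plain delimited tables (TSV) for concentration series — a ``time_s``
  column plus one column per channel.

Events tables (``onset_s``, ``duration_s``, ``condition``,
``screen_index``), behavioral selection logs and square connectivity
matrices are all TSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .containers import HemoSeries, RawIntensitySeries
from .errors import FormatError, LayoutError
from .layout import ChannelLayout, default_layout

EVENT_COLUMNS = ["onset_s", "duration_s", "condition", "screen_index"]


# --------------------------------------------------------------------------
# SNIRF


def write_snirf(raw: RawIntensitySeries, path: str | Path) -> Path:
    """Write intensities and stimulus blocks to a SNIRF v1.0 file."""
    path = Path(path)
    C, W, T = raw.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        data = nirs.create_group("data1")
        flat = raw.data.reshape(C * W, T).T  # time x measurement, channel-major
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(T) / raw.rate_hz)
        m = 1
        for c in range(C):
            src, det = raw.layout.source_detector[c]
            for w in range(W):
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=src)
                ml.create_dataset("detectorIndex", data=det)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.layout.wavelengths_nm))
        n_opt = max(max(sd) for sd in raw.layout.source_detector)
        probe.create_dataset("sourcePos3D", data=np.zeros((n_opt, 3)))
        probe.create_dataset("detectorPos3D", data=np.zeros((n_opt, 3)))
        if raw.markers is not None and len(raw.markers):
            for k, (cond, grp) in enumerate(raw.markers.groupby("condition"), start=1):
                stim = nirs.create_group(f"stim{k}")
                stim.create_dataset("name", data=str(cond))
                cols = np.column_stack(
                    [
                        grp["onset_s"].to_numpy(float),
                        grp["duration_s"].to_numpy(float),
                        grp.get("screen_index", pd.Series(np.ones(len(grp)))).to_numpy(float),
                    ]
                )
                stim.create_dataset("data", data=cols)
    return path


def _require(h5: h5py.Group, key: str):
    if key not in h5:
        raise FormatError(f"SNIRF file is missing required field '{h5.name}/{key}'")
    return h5[key]


def read_snirf(path: str | Path, layout: ChannelLayout | None = None) -> RawIntensitySeries:
    """Read a SNIRF intensity file back into a :class:`RawIntensitySeries`."""
    layout = layout or default_layout()
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"not a readable HDF5/SNIRF file: {path} ({exc})") from exc
    with f:
        nirs = _require(f, "nirs")
        data = _require(nirs, "data1")
        flat = np.asarray(_require(data, "dataTimeSeries"))
        time = np.asarray(_require(data, "time"))
        if flat.ndim != 2 or flat.shape[0] != time.shape[0]:
            raise FormatError("dataTimeSeries/time shape mismatch")
        ml_keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(ml_keys) != flat.shape[1]:
            raise FormatError("measurementList count does not match dataTimeSeries columns")
        wl_index = np.array(
            [int(np.asarray(_require(data[k], "wavelengthIndex"))) for k in ml_keys]
        )
        n_wl = wl_index.max()
        if flat.shape[1] % n_wl:
            raise FormatError("measurement count is not a multiple of the wavelength count")
        n_ch = flat.shape[1] // n_wl
        if n_ch != layout.n_channels:
            raise LayoutError(
                f"{n_ch} channels in file, {layout.n_channels} expected by layout"
            )
        cube = flat.T.reshape(n_ch, n_wl, -1)
        if len(time) > 1:
            rate = 1.0 / np.median(np.diff(time))
        else:
            raise FormatError("time axis has fewer than 2 samples")
        marker_rows = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            name = _require(stim, "name")[()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            arr = np.atleast_2d(np.asarray(_require(stim, "data")))
            for row in arr:
                marker_rows.append(
                    {
                        "onset_s": float(row[0]),
                        "duration_s": float(row[1]),
                        "condition": name,
                        "screen_index": int(row[2]) if len(row) > 2 else 1,
                    }
                )
        markers = (
            pd.DataFrame(marker_rows).sort_values("onset_s").reset_index(drop=True)
            if marker_rows
            else None
        )
        return RawIntensitySeries(
            data=cube, rate_hz=float(rate), layout=layout, markers=markers
        )


# --------------------------------------------------------------------------
# delimited tables


def write_hemo_tsv(series: HemoSeries, path: str | Path) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_hemo_tsv(path: str | Path, layout: ChannelLayout | None = None) -> HemoSeries:
    layout = layout or default_layout()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse delimited table {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise FormatError(f"{path} is missing the 'time_s' column")
    chan_cols = [c for c in df.columns if c != "time_s"]
    if len(chan_cols) != layout.n_channels:
        raise LayoutError(
            f"{len(chan_cols)} channel columns in file, {layout.n_channels} expected"
        )
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise FormatError(f"{path} holds fewer than 2 samples")
    rate = 1.0 / np.median(np.diff(t))
    ordered = [c for c in layout.channels if c in chan_cols]
    if len(ordered) != layout.n_channels:
        raise LayoutError("channel column names do not match the layout labels")
    return HemoSeries(hbo=df[ordered].to_numpy(float).T, rate_hz=float(rate), layout=layout)


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events table {path} is missing columns {sorted(missing)}")
    return df


def write_behavior_tsv(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.to_csv(path, sep="\t", index=False)
    return path


def read_behavior_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "condition", "rt_ms", "price_tier"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"behavior log {path} is missing columns {sorted(missing)}")
    return df


def write_matrix_tsv(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep="\t", index_label="node")
    return path


def read_matrix_tsv(path: str | Path) -> ConnectivityMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col="node")
    except Exception as exc:
        raise FormatError(f"cannot parse matrix table {path}: {exc}") from exc
    if list(df.index) != list(df.columns):
        raise FormatError(f"matrix table {path} must be square with matching labels")
    return ConnectivityMatrix(values=df.to_numpy(float), labels=tuple(df.columns))


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    edges.to_csv(path, sep="\t", index=False)
    return path
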