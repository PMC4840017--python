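"""Readers and writers for optical recordings and hemoglobin series.

Two dialects are supported: a SNIRF-style HDF5 container (optical-density
time series plus probe geometry, following the /nirs/data1 + /nirs/probe
group layout of the SNIRF specification) and plain wide CSV/TSV tables whose
first column is time in seconds.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .optics import HbSeries, OpticalRecording
from .scalp import ProbeLayout

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_od_table",
    "read_od_table",
    "write_hb_table",
    "read_hb_table",
]


def write_snirf(path, rec: OpticalRecording) -> None:
    """Write an optical recording (+ geometry) as a SNIRF-style HDF5 file."""
    layout = rec.layout
    if layout is None or layout.channel_pairs is None:
        raise ValueError("SNIRF export needs a layout with source-detector pairs")
    M, J = rec.n_samples, rec.n_channels
    data = np.empty((M, 2 * J))
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        k = 0
        for wl_idx in (1, 2):
            for j, (s, d) in enumerate(layout.channel_pairs):
                data[:, k] = rec.od[wl_idx - 1, :, j]
                ml = d1.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=s + 1)
                ml.create_dataset("detectorIndex", data=d + 1)
                ml.create_dataset("wavelengthIndex", data=wl_idx)
                ml.create_dataset("dataType", data=1)
                k += 1
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(M) / rec.fs)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
        probe.create_dataset("sourcePos3D", data=layout.source_pos)
        probe.create_dataset("detectorPos3D", data=layout.detector_pos)


def read_snirf(path) -> OpticalRecording:
    """Read a SNIRF-style HDF5 file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"], dtype=float)
        time = np.asarray(d1["time"], dtype=float)
        fs = 1.0 / float(np.median(np.diff(time)))
        probe = f["nirs/probe"]
        wavelengths = tuple(float(w) for w in np.asarray(probe["wavelengths"]))
        src = np.asarray(probe["sourcePos3D"], dtype=float)
        det = np.asarray(probe["detectorPos3D"], dtype=float)
        cols = []
        for k in range(data.shape[1]):
            ml = d1[f"measurementList{k + 1}"]
            cols.append(
                (
                    int(np.asarray(ml["sourceIndex"])) - 1,
                    int(np.asarray(ml["detectorIndex"])) - 1,
                    int(np.asarray(ml["wavelengthIndex"])),
                )
            )
    pairs = list(dict.fromkeys((s, d) for s, d, _ in cols))  # order-preserving
    pair_index = {p: j for j, p in enumerate(pairs)}
    M, J = data.shape[0], len(pairs)
    od = np.zeros((2, M, J))
    for k, (s, d, wl) in enumerate(cols):
        od[wl - 1, :, pair_index[(s, d)]] = data[:, k]
    layout = ProbeLayout(
        source_pos=src, detector_pos=det, channel_pairs=list(pairs)
    )
    return OpticalRecording(
        od=od,
        fs=fs,
        channel_ids=list(layout.channel_ids),
        wavelengths=wavelengths,
        layout=layout,
    )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_od_table(path, rec: OpticalRecording) -> None:
    """Wide table: time column plus one ``<channel>@<wavelength>`` column each."""
    M = rec.n_samples
    out = {"time": np.arange(M) / rec.fs}
    for w, wl in enumerate(rec.wavelengths):
        for j, cid in enumerate(rec.channel_ids):
            out[f"{cid}@{wl:g}"] = rec.od[w, :, j]
    pd.DataFrame(out).to_csv(path, sep=_sep_for(path), index=False)


def read_od_table(path, layout: ProbeLayout | None = None) -> OpticalRecording:
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.columns[0] != "time":
        raise ValueError("first column must be 'time' [s]")
    time = df["time"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(time)))
    wl_map: dict[float, dict[str, np.ndarray]] = {}
    for col in df.columns[1:]:
        cid, wl_s = col.rsplit("@", 1)
        wl_map.setdefault(float(wl_s), {})[cid] = df[col].to_numpy(float)
    if len(wl_map) != 2:
        raise ValueError(f"expected 2 wavelengths, found {sorted(wl_map)}")
    wls = sorted(wl_map)
    channels = list(wl_map[wls[0]])
    od = np.stack(
        [np.column_stack([wl_map[w][c] for c in channels]) for w in wls]
    )
    return OpticalRecording(
        od=od, fs=fs, channel_ids=channels, wavelengths=(wls[0], wls[1]), layout=layout
    )


def write_hb_table(path, series: HbSeries) -> None:
    """Wide table: time plus ``<channel>_hbo`` and ``<channel>_hbr`` columns."""
    out = {"time": np.arange(series.n_samples) / series.fs}
    for j, cid in enumerate(series.channel_ids):
        out[f"{cid}_hbo"] = series.hbo[:, j]
        out[f"{cid}_hbr"] = series.hbr[:, j]
    pd.DataFrame(out).to_csv(path, sep=_sep_for(path), index=False)


def read_hb_table(path) -> HbSeries:
    df = pd.read_csv(path, sep=_sep_for(path))
    time = df["time"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(time)))
    channels = []
    for col in df.columns[1:]:
        if col.endswith("_hbo"):
            channels.append(col[:-4])
    hbo = np.column_stack([df[f"{c}_hbo"].to_numpy(float) for c in channels])
    hbr = np.column_stack([df[f"{c}_hbr"].to_numpy(float) for c in channels])
    return HbSeries(hbo=hbo, hbr=hbr, fs=fs, channel_ids=channels)
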