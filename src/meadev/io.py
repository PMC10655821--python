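"""On-disk formats: HDF5 voltage stores (with a binary+JSON sidecar
fallback), tidy CSV spike/burst/feature tables.

Schema (version 1): one dataset per electrode recording, named
``w{well}_e{electrode}_d{div}``, float64 µV samples, with attributes
``sampling_rate``, ``well``, ``electrode``, ``div``, ``genotype``,
``batch``.  The sidecar fallback is a ``.json`` manifest next to a flat
little-endian float64 ``.bin`` with per-dataset offsets.

Spike times are seconds from recording start (0-based); burst intervals are
half-open ``[t_start, t_end)``.  CSVs are comma-separated UTF-8 with a
header row; missing values are empty fields.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .core import Burst, NetworkBurst, RecordingMeta, SpikeTrain, \
    VoltageRecording

__all__ = [
    "SCHEMA_VERSION",
    "write_voltage_h5",
    "write_voltage_sidecar",
    "read_voltage_store",
    "trains_to_frame",
    "frame_to_trains",
    "bursts_to_frame",
    "network_bursts_to_frame",
]

SCHEMA_VERSION = 1
_META_ATTRS = ("well", "electrode", "div", "genotype", "batch")


def _ds_name(meta: RecordingMeta) -> str:
    return f"w{meta.well:03d}_e{meta.electrode:02d}_d{meta.div:02d}"


def write_voltage_h5(recordings, path) -> None:
    """Write voltage recordings to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        for rec in recordings:
            ds = fh.create_dataset(_ds_name(rec.meta), data=rec.samples)
            ds.attrs["sampling_rate"] = rec.sampling_rate
            for name in _META_ATTRS:
                ds.attrs[name] = getattr(rec.meta, name)


def write_voltage_sidecar(recordings, path) -> None:
    """Write recordings as a flat binary + JSON manifest pair.

    ``path`` names the manifest (``.json``); samples go to the same stem
    with ``.bin``.
    """
    path = str(path)
    stem = path[:-5] if path.endswith(".json") else path
    manifest = {"schema_version": SCHEMA_VERSION, "dtype": "<f8",
                "datasets": []}
    offset = 0
    with open(stem + ".bin", "wb") as bf:
        for rec in recordings:
            samples = np.ascontiguousarray(rec.samples, dtype="<f8")
            bf.write(samples.tobytes())
            entry = {"name": _ds_name(rec.meta), "offset": offset,
                     "n_samples": int(samples.size),
                     "sampling_rate": rec.sampling_rate}
            entry.update({k: getattr(rec.meta, k) for k in _META_ATTRS})
            manifest["datasets"].append(entry)
            offset += samples.size
    with open(stem + ".json", "w") as mf:
        json.dump(manifest, mf, indent=1)


def read_voltage_store(path) -> list[VoltageRecording]:
    """Read an HDF5 or sidecar voltage store; schema-version checked."""
    path = str(path)
    if path.endswith(".json") or (not os.path.exists(path)
                                  and os.path.exists(path + ".json")):
        return _read_sidecar(path if path.endswith(".json")
                             else path + ".json")
    if h5py.is_hdf5(path):
        return _read_h5(path)
    raise ValueError(f"{path}: neither an HDF5 container nor a JSON sidecar")


def _read_h5(path) -> list[VoltageRecording]:
    out = []
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version}")
        for name in sorted(fh):
            ds = fh[name]
            if "sampling_rate" not in ds.attrs:
                raise ValueError(f"dataset {name!r}: missing sampling_rate")
            for attr in _META_ATTRS:
                if attr not in ds.attrs:
                    raise ValueError(f"dataset {name!r}: missing {attr}")
            meta = RecordingMeta(
                well=int(ds.attrs["well"]), electrode=int(ds.attrs["electrode"]),
                div=int(ds.attrs["div"]), genotype=str(ds.attrs["genotype"]),
                batch=str(ds.attrs["batch"]))
            out.append(VoltageRecording(samples=ds[()],
                                        sampling_rate=float(
                                            ds.attrs["sampling_rate"]),
                                        meta=meta))
    return out


def _read_sidecar(manifest_path) -> list[VoltageRecording]:
    with open(manifest_path) as mf:
        manifest = json.load(mf)
    if int(manifest.get("schema_version", -1)) != SCHEMA_VERSION:
        raise ValueError("unsupported sidecar schema version")
    stem = manifest_path[:-5]
    data = np.fromfile(stem + ".bin", dtype=manifest.get("dtype", "<f8"))
    out = []
    for entry in manifest["datasets"]:
        for attr in ("sampling_rate",) + _META_ATTRS:
            if attr not in entry:
                raise ValueError(
                    f"dataset {entry.get('name', '?')!r}: missing {attr}")
        lo = entry["offset"]
        hi = lo + entry["n_samples"]
        if hi > data.size:
            raise ValueError(f"dataset {entry['name']!r}: truncated samples")
        meta = RecordingMeta(well=int(entry["well"]),
                             electrode=int(entry["electrode"]),
                             div=int(entry["div"]),
                             genotype=str(entry["genotype"]),
                             batch=str(entry["batch"]))
        out.append(VoltageRecording(samples=data[lo:hi].copy(),
                                    sampling_rate=float(
                                        entry["sampling_rate"]),
                                    meta=meta))
    return out


# ---------------------------------------------------------------------------
# tidy tables
# ---------------------------------------------------------------------------

def trains_to_frame(trains) -> pd.DataFrame:
    """One row per spike: well, electrode, div, genotype, batch, t, amplitude."""
    rows = []
    for tr in trains:
        m = tr.meta
        amps = tr.amplitudes if tr.amplitudes is not None \
            else np.full(tr.n_spikes, np.nan)
        rows.append(pd.DataFrame({
            "well": m.well, "electrode": m.electrode, "div": m.div,
            "genotype": m.genotype, "batch": m.batch,
            "t": tr.times, "amplitude": amps,
            "duration": tr.duration}))
    if not rows:
        return pd.DataFrame(columns=["well", "electrode", "div", "genotype",
                                     "batch", "t", "amplitude", "duration"])
    return pd.concat(rows, ignore_index=True)


def frame_to_trains(df: pd.DataFrame) -> list[SpikeTrain]:
    out = []
    keys = ["well", "electrode", "div", "genotype", "batch"]
    for (well, elec, div, geno, batch), g in df.groupby(keys, sort=True):
        g = g.sort_values("t")
        meta = RecordingMeta(well=int(well), electrode=int(elec),
                             div=int(div), genotype=str(geno),
                             batch=str(batch))
        amps = g["amplitude"].to_numpy(dtype=float)
        out.append(SpikeTrain(times=g["t"].to_numpy(dtype=float),
                              duration=float(g["duration"].iloc[0]),
                              amplitudes=None if np.isnan(amps).all()
                              else amps,
                              meta=meta))
    return out


def bursts_to_frame(bursts_by_key) -> pd.DataFrame:
    """``bursts_by_key``: mapping (well, div) -> {electrode: [Burst, ...]}."""
    rows = []
    for (well, div), per_elec in bursts_by_key.items():
        for elec, blist in per_elec.items():
            for b in blist:
                rows.append({"well": well, "div": div, "electrode": elec,
                             "t_start": b.t_start, "t_end": b.t_end,
                             "n_spikes": b.n_spikes})
    return pd.DataFrame(rows, columns=["well", "div", "electrode",
                                       "t_start", "t_end", "n_spikes"])


def network_bursts_to_frame(nb_by_key) -> pd.DataFrame:
    rows = []
    for (well, div), nbs in nb_by_key.items():
        for nb in nbs:
            rows.append({"well": well, "div": div,
                         "t_start": nb.t_start, "t_end": nb.t_end,
                         "n_electrodes": nb.n_electrodes,
                         "electrodes": ";".join(map(str,
                                                    sorted(nb.electrodes))),
                         "n_spikes": nb.n_spikes})
    return pd.DataFrame(rows, columns=["well", "div", "t_start", "t_end",
                                       "n_electrodes", "electrodes",
                                       "n_spikes"])
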