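"""Reading and writing of image series, ROIs, ground truth and sweeps.

Image series are stored as multi-page TIFF with pages ordered
t → z → channel, plus a JSON sidecar (same stem, ``.json``) carrying the
geometry (pixel size, z-step, frame interval), the channel map and the
stimulus onset.  ROI masks are stored as a uint8 multi-page TIFF with the
soma planes first, then the process planes.  Sweeps are stored either as a
long-format CSV (columns sweep_id, time_s, value) with a JSON sidecar of
per-sweep attributes, or as an HDF5 file with one dataset per sweep and
the attributes attached to each dataset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import ImagingSeries, ROISet, Sweep, SweepSet
from .synth.phantom import GroundTruth

__all__ = [
    "save_imaging_series",
    "load_imaging_series",
    "save_rois",
    "load_rois",
    "save_ground_truth",
    "load_ground_truth",
    "save_sweeps_csv",
    "load_sweeps_csv",
    "save_sweeps_hdf5",
    "load_sweeps_hdf5",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_imaging_series(path: str | Path, series: ImagingSeries) -> Path:
    """Write a series to TIFF (pages t→z→channel) plus JSON sidecar."""
    path = Path(path)
    nt, nz, ny, nx, nc = series.data.shape
    pages = np.transpose(series.data, (0, 1, 4, 2, 3)).reshape(-1, ny, nx)
    tifffile.imwrite(path, pages.astype(np.float32))
    meta = {
        "page_order": "t,z,channel",
        "shape_tzyxc": [nt, nz, ny, nx, nc],
        "pixel_size_um": series.pixel_size,
        "z_step_um": series.z_step,
        "frame_interval_s": series.frame_interval,
        "channel_roles": series.channel_roles,
        "stimulus_onset_frame": series.stimulus_onset_frame,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_imaging_series(path: str | Path) -> ImagingSeries:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    nt, nz, ny, nx, nc = meta["shape_tzyxc"]
    pages = tifffile.imread(path).reshape(nt, nz, nc, ny, nx)
    data = np.transpose(pages, (0, 1, 3, 4, 2)).astype(float)
    return ImagingSeries(
        data=data,
        pixel_size=meta["pixel_size_um"],
        z_step=meta["z_step_um"],
        frame_interval=meta["frame_interval_s"],
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        stimulus_onset_frame=meta["stimulus_onset_frame"],
    )


def save_rois(path: str | Path, rois: ROISet) -> Path:
    """Write soma + process masks as a uint8 TIFF (soma planes first)."""
    path = Path(path)
    stacked = np.concatenate(
        [rois.soma_mask.astype(np.uint8), rois.process_mask.astype(np.uint8)]
    )
    tifffile.imwrite(path, stacked)
    _sidecar(path).write_text(
        json.dumps({"layout": "soma_then_process", "nz": rois.soma_mask.shape[0]})
    )
    return path


def load_rois(path: str | Path) -> ROISet:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stacked = tifffile.imread(path)
    nz = meta["nz"]
    return ROISet(
        soma_mask=stacked[:nz].astype(bool), process_mask=stacked[nz:].astype(bool)
    )


def save_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    record = dataclasses.asdict(truth)
    for key, val in record.items():
        if isinstance(val, np.ndarray):
            record[key] = val.tolist()
    path.write_text(json.dumps(record, indent=2, default=str))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    record = json.loads(Path(path).read_text())
    for key in ("v_series", "cl_series", "ratio_series", "vf_truth", "shifts"):
        if record.get(key) is not None:
            record[key] = np.asarray(record[key])
    return GroundTruth(**record)


def _sweep_attrs(sweep: Sweep) -> dict:
    return {
        "sampling_rate": sweep.sampling_rate,
        "protocol_tag": sweep.protocol_tag,
        "kind": sweep.kind,
        "repeat_index": sweep.repeat_index,
        "meta": sweep.meta,
    }


def save_sweeps_csv(path: str | Path, sweep_set: SweepSet) -> Path:
    """Long-format CSV (sweep_id, time_s, value) + JSON sidecar of attributes."""
    path = Path(path)
    frames = []
    attrs = {"protocol": sweep_set.protocol, "meta": sweep_set.meta, "sweeps": {}}
    for si, sweep in enumerate(sweep_set):
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": si,
                    "time_s": sweep.times(),
                    "value": sweep.samples,
                }
            )
        )
        attrs["sweeps"][str(si)] = _sweep_attrs(sweep)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(attrs, indent=2))
    return path


def load_sweeps_csv(path: str | Path) -> SweepSet:
    path = Path(path)
    attrs = json.loads(_sidecar(path).read_text())
    table = pd.read_csv(path)
    sweeps = []
    for si, group in table.groupby("sweep_id"):
        a = attrs["sweeps"][str(si)]
        sweeps.append(
            Sweep(
                samples=group["value"].to_numpy(),
                sampling_rate=a["sampling_rate"],
                protocol_tag=a["protocol_tag"],
                kind=a["kind"],
                repeat_index=a["repeat_index"],
                meta=a["meta"],
            )
        )
    return SweepSet(sweeps=sweeps, protocol=attrs["protocol"], meta=attrs["meta"])


def save_sweeps_hdf5(path: str | Path, sweep_set: SweepSet) -> Path:
    """HDF5 with one dataset per sweep; attributes on each dataset."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["protocol"] = sweep_set.protocol
        fh.attrs["meta"] = json.dumps(sweep_set.meta)
        for si, sweep in enumerate(sweep_set):
            ds = fh.create_dataset(f"sweep_{si:03d}", data=sweep.samples)
            ds.attrs["sampling_rate"] = sweep.sampling_rate
            ds.attrs["protocol_tag"] = sweep.protocol_tag
            ds.attrs["kind"] = sweep.kind
            ds.attrs["repeat_index"] = sweep.repeat_index
            ds.attrs["meta"] = json.dumps(sweep.meta)
    return path


def load_sweeps_hdf5(path: str | Path) -> SweepSet:
    sweeps = []
    with h5py.File(path, "r") as fh:
        protocol = fh.attrs["protocol"]
        meta = json.loads(fh.attrs["meta"])
        for name in sorted(fh.keys()):
            ds = fh[name]
            sweeps.append(
                Sweep(
                    samples=ds[()],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    protocol_tag=str(ds.attrs["protocol_tag"]),
                    kind=str(ds.attrs["kind"]),
                    repeat_index=int(ds.attrs["repeat_index"]),
                    meta=json.loads(ds.attrs["meta"]),
                )
            )
    return SweepSet(sweeps=sweeps, protocol=str(protocol), meta=meta)
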