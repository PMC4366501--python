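"""File contracts for traces, point patterns, rasters and reports.

All formats are plain text (CSV + JSON sidecars) or HDF5:

* traces: CSV with a ``time_s`` column plus one ``roi_<k>`` column per
  fibre; sampling rate, stimulus times and units travel in a JSON
  sidecar (``<stem>.meta.json``) or, for HDF5, as attributes.
* point patterns: CSV with ``x_um, y_um[, label]`` columns and the
  bounded region in a leading ``# region: x0 y0 width height`` comment.
* fields of view: CSV with ``fibre_id, x_um, y_um, responder, fov_id``.
* rasters: CSV with ``fibre_id`` plus ``trial_<j>`` 0/1 columns.
* reports: deterministic JSON (sorted keys, fixed float formatting).

Round trips are lossless to full float precision (float64 ``repr``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd

from .coactivity import FieldOfView
from .core import PointPattern, Region, ResponseRaster, Trace

__all__ = [
    "write_traces",
    "read_traces",
    "write_points",
    "read_points",
    "write_raster",
    "read_raster",
    "write_fovs",
    "read_fovs",
    "write_report",
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------- traces

def write_traces(traces: Sequence[Trace], path: PathLike) -> None:
    """Write traces to CSV (+ ``.meta.json`` sidecar) or HDF5 by suffix."""
    path = Path(path)
    if not traces:
        raise ValueError("no traces to write")
    fs = traces[0].sampling_rate
    if any(t.sampling_rate != fs or t.n_samples != traces[0].n_samples for t in traces):
        raise ValueError("all traces in one file must share rate and length")
    data = np.column_stack([t.samples for t in traces])
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("traces", data=data)
            ds.attrs["sampling_rate_hz"] = fs
            ds.attrs["units"] = traces[0].units
            f.create_dataset("stimulus_times_s", data=traces[0].stimulus_times)
        return
    df = pd.DataFrame(
        {"time_s": traces[0].times}
        | {f"roi_{k}": t.samples for k, t in enumerate(traces)}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": fs,
        "units": traces[0].units,
        "stimulus_times_s": list(map(float, traces[0].stimulus_times)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_traces(path: PathLike) -> List[Trace]:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["traces"][...]
            fs = float(f["traces"].attrs["sampling_rate_hz"])
            units = str(f["traces"].attrs["units"])
            stims = f["stimulus_times_s"][...]
        return [
            Trace(data[:, k], fs, stimulus_times=stims, units=units)
            for k in range(data.shape[1])
        ]
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s"], path)
    t = df["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs = float(meta["sampling_rate_hz"])
        units = meta.get("units", "dff")
        stims = np.asarray(meta.get("stimulus_times_s", []), dtype=float)
    else:
        fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        units, stims = "dff", np.empty(0)
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    if not roi_cols:
        raise ValueError(f"{path}: no roi_<k> columns found")
    return [
        Trace(df[c].to_numpy(), fs, stimulus_times=stims, units=units)
        for c in sorted(roi_cols, key=lambda c: int(c.split("_")[1]))
    ]


# ---------------------------------------------------------------- points

def write_points(pattern: PointPattern, path: PathLike) -> None:
    path = Path(path)
    r = pattern.region
    cols: Dict[str, np.ndarray] = {
        "x_um": pattern.points[:, 0],
        "y_um": pattern.points[:, 1],
    }
    if pattern.labels is not None:
        cols["label"] = pattern.labels
    with open(path, "w") as fh:
        fh.write(f"# region: {float(r.x0)!r} {float(r.y0)!r} {float(r.width)!r} {float(r.height)!r}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def read_points(path: PathLike) -> PointPattern:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# region:"):
            raise ValueError(f"{path}: missing '# region:' header line")
        vals = first.split(":", 1)[1].split()
        region = Region(*map(float, vals))
        df = pd.read_csv(fh, float_precision="round_trip")
    _require_columns(df, ["x_um", "y_um"], path)
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(pts)):
        bad = int(np.where(~np.isfinite(pts).all(axis=1))[0][0])
        raise ValueError(f"{path}: non-finite coordinate at row {bad}")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return PointPattern(pts, region, labels)


# ---------------------------------------------------------------- rasters

def write_raster(raster: ResponseRaster, path: PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(
        raster.responses.astype(int),
        columns=[f"trial_{j}" for j in range(raster.n_trials)],
    )
    df.insert(0, "fibre_id", np.arange(raster.n_fibres))
    with open(path, "w") as fh:
        stims = " ".join(repr(float(s)) for s in raster.stimulus_times)
        fh.write(f"# fov_id: {raster.fov_id}\n# stimulus_times_s: {stims}\n")
        df.to_csv(fh, index=False)


def read_raster(path: PathLike) -> ResponseRaster:
    path = Path(path)
    with open(path) as fh:
        fov_line = fh.readline()
        stim_line = fh.readline()
        if not fov_line.startswith("# fov_id:") or not stim_line.startswith(
            "# stimulus_times_s:"
        ):
            raise ValueError(f"{path}: malformed raster header")
        fov_id = int(fov_line.split(":", 1)[1])
        stim_str = stim_line.split(":", 1)[1].split()
        stims = np.asarray([float(s) for s in stim_str])
        df = pd.read_csv(fh, float_precision="round_trip")
    _require_columns(df, ["fibre_id"], path)
    trial_cols = [c for c in df.columns if c.startswith("trial_")]
    if not trial_cols:
        raise ValueError(f"{path}: no trial_<j> columns found")
    trial_cols = sorted(trial_cols, key=lambda c: int(c.split("_")[1]))
    resp = df[trial_cols].to_numpy(dtype=int).astype(bool)
    return ResponseRaster(resp, stimulus_times=stims, fov_id=fov_id)


# ---------------------------------------------------------------- FOVs

def write_fovs(fovs: Sequence[FieldOfView], path: PathLike) -> None:
    """Write fibre geometry + responder flags for many FOVs to one CSV."""
    path = Path(path)
    rows = []
    for f in fovs:
        for i in range(f.n_labelled):
            rows.append(
                {
                    "fibre_id": i,
                    "x_um": f.pattern.points[i, 0],
                    "y_um": f.pattern.points[i, 1],
                    "responder": int(f.responder[i]),
                    "fov_id": f.fov_id,
                }
            )
    r0 = fovs[0].pattern.region
    with open(path, "w") as fh:
        fh.write(f"# region: {float(r0.x0)!r} {float(r0.y0)!r} {float(r0.width)!r} {float(r0.height)!r}\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.17g")


def read_fovs(
    path: PathLike, rasters: Optional[Dict[int, ResponseRaster]] = None
) -> List[FieldOfView]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# region:"):
            raise ValueError(f"{path}: missing '# region:' header line")
        region = Region(*map(float, first.split(":", 1)[1].split()))
        df = pd.read_csv(fh, float_precision="round_trip")
    _require_columns(df, ["fibre_id", "x_um", "y_um", "responder", "fov_id"], path)
    fovs = []
    for fov_id, grp in df.groupby("fov_id", sort=True):
        pts = grp.sort_values("fibre_id")[["x_um", "y_um"]].to_numpy(dtype=float)
        if np.any(~np.isfinite(pts)):
            raise ValueError(f"{path}: non-finite coordinate in fov {fov_id}")
        flags = grp.sort_values("fibre_id")["responder"].to_numpy(dtype=int).astype(bool)
        fovs.append(
            FieldOfView(
                pattern=PointPattern(pts, region),
                responder=flags,
                raster=None if rasters is None else rasters.get(int(fov_id)),
                fov_id=int(fov_id),
            )
        )
    return fovs


# ---------------------------------------------------------------- reports

def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(results: dict, path: PathLike) -> None:
    """Write an analysis report as deterministic JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(results), indent=2, sort_keys=True) + "\n")
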