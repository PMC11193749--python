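"""Interchange file formats replacing the instrument's proprietary output.

Force-extension traces travel as CSV (header ``time_s,force_pN,eed_um``) or
HDF5 (group ``/force_trace`` with one dataset per column).  Kymographs
travel as HDF5 (``/photons`` integer array, physical calibration in attrs)
with optional single-channel 16-bit TIFF export.  Simulation truth is JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from polfx.exchange_simulator import SimulationTruth
from polfx.kymo_registration import Kymograph
from polfx.polymer_models import ForceExtensionTrace

__all__ = [
    "write_force_csv",
    "read_force_csv",
    "write_force_hdf5",
    "read_force_hdf5",
    "write_kymograph_hdf5",
    "read_kymograph_hdf5",
    "write_kymograph_tiff",
    "write_truth_json",
    "read_truth_json",
]

FORCE_COLUMNS = ["time_s", "force_pN", "eed_um"]


def write_force_csv(trace: ForceExtensionTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "force_pN": trace.force, "eed_um": trace.eed}
    ).to_csv(path, index=False)


def read_force_csv(path) -> ForceExtensionTrace:
    df = pd.read_csv(path)
    missing = [c for c in FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"force CSV missing columns: {missing}")
    return ForceExtensionTrace(
        time=df["time_s"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        eed=df["eed_um"].to_numpy(),
    )


def write_force_hdf5(trace: ForceExtensionTrace, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("force_trace")
        g.create_dataset("time_s", data=trace.time)
        g.create_dataset("force_pN", data=trace.force)
        g.create_dataset("eed_um", data=trace.eed)
        g.attrs["columns"] = FORCE_COLUMNS


def read_force_hdf5(path) -> ForceExtensionTrace:
    with h5py.File(path, "r") as f:
        g = f["force_trace"]
        return ForceExtensionTrace(
            time=g["time_s"][:], force=g["force_pN"][:], eed=g["eed_um"][:]
        )


def write_kymograph_hdf5(kymo: Kymograph, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("photons", data=kymo.photons.astype(np.int64))
        d.attrs["line_time_s"] = kymo.line_time
        d.attrs["pixel_size_um"] = kymo.pixel_size
        d.attrs["origin_um"] = kymo.origin_position
        d.attrs["bead_band_pixels"] = kymo.bead_band_pixels


def read_kymograph_hdf5(path) -> Kymograph:
    with h5py.File(path, "r") as f:
        d = f["photons"]
        return Kymograph(
            photons=d[:],
            line_time=float(d.attrs["line_time_s"]),
            pixel_size=float(d.attrs["pixel_size_um"]),
            origin_position=float(d.attrs.get("origin_um", 0.0)),
            bead_band_pixels=int(d.attrs.get("bead_band_pixels", 0)),
        )


def write_kymograph_tiff(kymo: Kymograph, path) -> None:
    """Single-channel 16-bit TIFF export (counts clipped at 65535)."""
    tifffile.imwrite(path, np.clip(kymo.photons, 0, 65535).astype(np.uint16))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def write_truth_json(truth: SimulationTruth, path) -> None:
    doc = {
        "config": truth.config.model_dump(),
        "time": truth.time.tolist(),
        "force": truth.force.tolist(),
        "basepairs": truth.basepairs.tolist(),
        "ss_fraction": truth.ss_fraction.tolist(),
        "junction_position_um": truth.junction_position_um.tolist(),
        "events": [
            {
                "t_bind": ev.t_bind,
                "t_unbind": ev.t_unbind,
                "labeled": ev.labeled,
                "t_bleach": _jsonable(ev.t_bleach),
                "sub_intervals": [list(s) for s in ev.sub_intervals],
            }
            for ev in truth.events
        ],
        "extra_binders": [
            {
                "kind": b.kind,
                "t_bind": b.t_bind,
                "t_unbind": b.t_unbind,
                "labeled": b.labeled,
                "t_bleach": _jsonable(b.t_bleach),
                "positions": b.positions.tolist(),
                "line_start": b.line_start,
            }
            for b in truth.extra_binders
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_truth_json(path) -> SimulationTruth:
    from polfx.exchange_simulator import BindingEvent, ExtraBinder, SimulationConfig

    doc = json.loads(Path(path).read_text())

    def _inf(v):
        return math.inf if v == "inf" else float(v)

    cfg_doc = doc["config"]
    cfg_doc["force_schedule"] = tuple(tuple(p) for p in cfg_doc["force_schedule"])
    return SimulationTruth(
        config=SimulationConfig(**cfg_doc),
        time=np.array(doc["time"]),
        force=np.array(doc["force"]),
        basepairs=np.array(doc["basepairs"]),
        ss_fraction=np.array(doc["ss_fraction"]),
        junction_position_um=np.array(doc["junction_position_um"]),
        events=[
            BindingEvent(
                t_bind=e["t_bind"],
                t_unbind=e["t_unbind"],
                labeled=e["labeled"],
                t_bleach=_inf(e["t_bleach"]),
                sub_intervals=[
                    (float(a), float(b), float(r), str(c))
                    for a, b, r, c in e["sub_intervals"]
                ],
            )
            for e in doc["events"]
        ],
        extra_binders=[
            ExtraBinder(
                kind=b["kind"],
                t_bind=b["t_bind"],
                t_unbind=b["t_unbind"],
                labeled=b["labeled"],
                t_bleach=_inf(b["t_bleach"]),
                positions=np.array(b["positions"]),
                line_start=b["line_start"],
            )
            for b in doc["extra_binders"]
        ],
    )
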