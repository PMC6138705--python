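"""Delimited-text and raw-binary I/O.

Traces and summary tables travel as tab-separated text with ``#``-prefixed
``key=value`` metadata headers; field snapshots and material grids as raw
little-endian binary with a JSON sidecar describing dims, dtype and cell
size.  Every writer embeds the seed and configuration hash when given one,
so any output can be regenerated from its header alone.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .transmission import TraceSet


def _format_meta(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _parse_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    return meta


def write_trace(path, trace: TraceSet, meta: dict | None = None) -> None:
    path = Path(path)
    meta_all = {
        "excitation": trace.excitation,
        "length_cm": trace.length_cm,
        "thickness_mm": trace.thickness_mm,
        "concentration_mol_l": trace.concentration_mol_l,
    }
    if trace.duration_s is not None:
        meta_all["duration_s"] = trace.duration_s
    if trace.frequency_hz is not None:
        meta_all["frequency_hz"] = trace.frequency_hz
    meta_all.update(meta or {})
    with open(path, "w") as fh:
        fh.write(_format_meta(meta_all))
        fh.write("t\tv_ref\tv_trans\n")
        np.savetxt(
            fh,
            np.column_stack([trace.times, trace.reference, trace.transmitted]),
            fmt="%.9e",
            delimiter="\t",
        )


def read_trace(path) -> TraceSet:
    path = Path(path)
    meta = _parse_meta(path)
    data = np.loadtxt(path, comments="#", skiprows=len(meta) + 1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] < 3:
        raise AnalysisError(f"{path}: expected columns t, v_ref, v_trans")
    return TraceSet(
        times=data[:, 0],
        reference=data[:, 1],
        transmitted=data[:, 2],
        excitation=meta.get("excitation", "square"),
        length_cm=float(meta.get("length_cm", 0.0)),
        thickness_mm=float(meta.get("thickness_mm", 0.0)),
        concentration_mol_l=float(meta.get("concentration_mol_l", 0.0)),
        duration_s=float(meta["duration_s"]) if "duration_s" in meta else None,
        frequency_hz=float(meta["frequency_hz"]) if "frequency_hz" in meta else None,
    )


def write_table(path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_format_meta(meta or {}))
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    meta = _parse_meta(Path(path))
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame, meta


def export_array(path, array: np.ndarray, meta: dict | None = None) -> None:
    """Raw little-endian binary plus a JSON sidecar (``<path>.json``)."""
    path = Path(path)
    arr = np.ascontiguousarray(array)
    arr.astype("<f8" if arr.dtype.kind == "f" else arr.dtype.str).tofile(path)
    sidecar = {
        "dims": list(arr.shape),
        "dtype": "<f8" if arr.dtype.kind == "f" else arr.dtype.str,
        "order": "C",
    }
    sidecar.update(meta or {})
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_array(path) -> tuple[np.ndarray, dict]:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    arr = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["dims"])
    return arr, sidecar


def write_probe_records(path, records, meta: dict | None = None) -> None:
    """One time column plus one value column per probe record."""
    if not records:
        raise AnalysisError("no records to write")
    cols = {"t": records[0].times}
    for rec in records:
        cols[f"{rec.quantity}@{','.join(map(str, rec.location))}"] = rec.values
    write_table(path, pd.DataFrame(cols), meta)
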