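"""Delimited-text readers/writers for traces, trajectories and reports.

All on-disk formats are plain text: a comment-prefixed provenance header
(``# key: value`` lines) followed by tab-separated columns.  Units are
fixed package-wide: ms, mV, pA, uM.  Floats are written with ``%.17g``
so a write -> read -> write round trip is byte-identical.  Headers carry
no timestamps, so re-running a seeded generator reproduces files
exactly.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cell import CellTrajectory
from .errors import DomainError
from .protocols import CurrentTrace

__all__ = [
    "provenance",
    "config_hash",
    "write_trace",
    "read_trace",
    "write_po_trace",
    "write_trajectory",
    "read_trajectory",
    "write_family",
    "read_family",
    "write_report",
]

_FLOAT_FMT = "%.17g"

TRAJECTORY_COLUMNS = (
    "time_ms", "V_mV", "I_TASK_pA", "I_CRAC_pA", "I_Kv13_pA", "I_IK_pA",
    "Ca_local_uM", "Ca_global_uM",
)


def _tool_version() -> str:
    try:
        return version("kv13tcell")
    except PackageNotFoundError:
        return "unknown"


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(**extra) -> dict:
    """Standard provenance header fields (no timestamps: reruns are identical)."""
    return {"tool": "kv13tcell", "version": _tool_version(), **extra}


def _write_table(path, columns: Sequence[str], data: np.ndarray, header: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: " + "\t".join(columns) + "\n")
        np.savetxt(fh, np.column_stack(data), fmt=_FLOAT_FMT, delimiter="\t")


def _read_table(path) -> tuple[np.ndarray, dict]:
    header: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if ": " in body:
            key, value = body.split(": ", 1)
            header[key] = value
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return data, header


def write_trace(path, trace: CurrentTrace, **meta) -> None:
    """Write a current trace as (time_ms, V_mV, I_pA) columns."""
    header = provenance(**meta, label=trace.label, dt_ms=trace.dt_ms)
    _write_table(path, ("time_ms", "V_mV", "I_pA"), (trace.t_ms, trace.v_mV, trace.i_pA), header)


def read_trace(path) -> tuple[CurrentTrace, dict]:
    data, header = _read_table(path)
    if data.shape[1] != 3:
        raise DomainError(f"{path}: expected 3 columns (time_ms, V_mV, I_pA)")
    t, v, i = data.T
    dt = float(header.get("dt_ms", t[1] - t[0] if t.size > 1 else 0.0))
    return CurrentTrace(dt_ms=dt, t_ms=t, i_pA=i, v_mV=v, label=header.get("label", "")), header


def write_po_trace(path, t_ms: np.ndarray, po: np.ndarray, **meta) -> None:
    """Write an open-probability time series as (time_ms, Po) columns."""
    _write_table(path, ("time_ms", "Po"), (t_ms, po), provenance(**meta))


def write_trajectory(path, traj: CellTrajectory, **meta) -> None:
    """Write a cell trajectory with the eight standard columns."""
    header = provenance(**meta, dt_ms=traj.dt_ms)
    _write_table(
        path,
        TRAJECTORY_COLUMNS,
        (traj.t_ms, traj.v_mV, traj.i_task_pA, traj.i_crac_pA, traj.i_kv_pA,
         traj.i_ik_pA, traj.ca_local_uM, traj.ca_global_uM),
        header,
    )


def read_trajectory(path) -> tuple[dict, dict]:
    """Read a trajectory file into a column-name -> array mapping."""
    data, header = _read_table(path)
    if data.shape[1] != len(TRAJECTORY_COLUMNS):
        raise DomainError(f"{path}: expected {len(TRAJECTORY_COLUMNS)} columns")
    return {name: data[:, k] for k, name in enumerate(TRAJECTORY_COLUMNS)}, header


def write_family(directory, traces: Iterable[CurrentTrace], **meta) -> list[Path]:
    """Write one file per sweep plus a JSON manifest.

    The manifest records the sweep files in order together with the
    provenance fields, so a family can be reloaded as a unit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for k, trace in enumerate(traces):
        name = f"sweep_{k:03d}.tsv"
        write_trace(directory / name, trace, **meta)
        files.append(directory / name)
    manifest = {
        "provenance": provenance(**meta),
        "sweeps": [f.name for f in files],
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files


def read_family(directory) -> tuple[list[CurrentTrace], dict]:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    traces = [read_trace(directory / name)[0] for name in manifest["sweeps"]]
    return traces, manifest


def write_report(path, report: dict) -> None:
    """Flat JSON-compatible key-value report."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
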