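"""Readers and writers for trace tables and structured results.

Tables travel as CSV with a small ``#``-prefixed provenance header (package
version, config hash, seed); structured configuration and results travel as
JSON.  The trace-table schema is::

    cell_id, frame, time_s, intensity [, group, stim_frame]

with 0-based frames in strictly increasing order per cell.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DataError, SchemaError
from .traces import GROUPS, IntensityTrace

__all__ = ["read_trace_table", "write_trace_table", "traces_to_frame",
           "provenance_header", "config_hash"]

REQUIRED_COLUMNS = ("cell_id", "frame", "time_s", "intensity")


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    parts = [f"mechanoca {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return "# " + " ".join(parts)


def write_trace_table(df: pd.DataFrame, path, seed: int | None = None,
                      config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        df.to_csv(fh, index=False)


def read_trace_table(path) -> list[IntensityTrace]:
    """Read and validate a per-cell trace table.

    Raises :class:`SchemaError` for missing columns and :class:`DataError`
    for non-monotone or duplicated frames, naming the offending cell.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table {path} is missing required column(s) "
                          f"{', '.join(missing)}")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.reset_index(drop=True)
        frames = sub["frame"].to_numpy()
        if len(frames) != len(np.unique(frames)):
            raise DataError(f"cell {cell_id!r}: duplicated frame index")
        if np.any(np.diff(frames) <= 0):
            raise DataError(f"cell {cell_id!r}: frame index not strictly increasing")
        if np.any(np.diff(frames) != 1):
            raise DataError(f"cell {cell_id!r}: gaps in frame index")
        group = "unlabeled"
        if "group" in sub.columns and isinstance(sub["group"].iloc[0], str):
            group = sub["group"].iloc[0]
            if group not in GROUPS:
                raise DataError(f"cell {cell_id!r}: unknown group {group!r}")
        stim_frame = int(sub["stim_frame"].iloc[0]) if "stim_frame" in sub.columns \
            else 10
        traces.append(IntensityTrace(
            cell_id=str(cell_id),
            frame_index=frames - frames[0],
            time=sub["time_s"].to_numpy(dtype=float),
            intensity=sub["intensity"].to_numpy(dtype=float),
            stim_frame=stim_frame,
            group=group,
        ))
    return traces


def traces_to_frame(traces: Iterable[IntensityTrace]) -> pd.DataFrame:
    """Inverse of :func:`read_trace_table` (without the provenance header)."""
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id, "frame": tr.frame_index,
            "time_s": tr.time, "intensity": tr.intensity,
            "group": tr.group, "stim_frame": tr.stim_frame,
        }))
    return pd.concat(rows, ignore_index=True)
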