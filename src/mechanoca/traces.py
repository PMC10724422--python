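"""Fluorescence trace features, cell classification and group averaging.

A recording is a per-cell time series of mean ROI intensity sampled at a
fixed frame interval, with a known number of pre-stimulus baseline frames.
The pipeline mirrors the standard Ca2+-imaging feature definitions:

* baseline ``I_basal``: mean raw intensity over the baseline frames
  immediately before stimulation (default: the 10 frames before the
  stimulus);
* amplitude: maximum of the normalized intensity ``I/I_basal`` over the
  post-stimulus frames;
* 50% decay time: time from the frame of the maximum to the first crossing
  of the mid-level between maximum and baseline, with linear interpolation
  between frames (a "half of maximum" variant is available through
  ``decay_mode="half_max"``).

Cells are classified geometrically relative to the photostimulated
rectangle: *target* cells overlap it, *neighbor* cells touch a target cell
but not the rectangle, and *other* cells do neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .exceptions import DataError, PreconditionError

__all__ = [
    "IntensityTrace",
    "TraceFeatures",
    "CellLayout",
    "normalize",
    "features",
    "classify_cells",
    "group_average",
    "correlate_features",
    "features_table",
]

logger = logging.getLogger(__name__)

GROUPS = ("target", "neighbor", "other", "unlabeled")

#: amplitude above which a cell is counted as a responder (QC plumbing)
RESPONDER_THRESHOLD = 1.2


@dataclass(frozen=True)
class IntensityTrace:
    """A per-cell fluorescence time series.

    ``stim_frame`` is the index of the first post-stimulus frame; frames
    ``0 .. stim_frame-1`` are baseline.  ``normalized`` records whether the
    intensities have already been divided by ``I_basal``.
    """

    cell_id: str
    frame_index: np.ndarray
    time: np.ndarray
    intensity: np.ndarray
    stim_frame: int
    group: str = "unlabeled"
    normalized: bool = False
    i_basal: float | None = None

    def __post_init__(self) -> None:
        fi = np.asarray(self.frame_index)
        if fi.size < 2 or np.any(np.diff(fi) != 1):
            raise DataError(
                f"cell {self.cell_id!r}: frame_index must be strictly increasing "
                "with no gaps"
            )
        if len(self.time) != fi.size or len(self.intensity) != fi.size:
            raise DataError(f"cell {self.cell_id!r}: ragged trace arrays")
        if not (1 <= self.stim_frame <= fi.size):
            raise DataError(
                f"cell {self.cell_id!r}: stim_frame must leave at least one "
                f"baseline frame, got {self.stim_frame!r}"
            )
        if self.group not in GROUPS:
            raise DataError(f"cell {self.cell_id!r}: unknown group {self.group!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)


@dataclass(frozen=True)
class TraceFeatures:
    """Derived features of a normalized trace."""

    cell_id: str
    i_basal: float
    amplitude: float
    decay50: float  # NaN when the trace never crosses the mid-level
    responder: bool
    group: str = "unlabeled"

    @property
    def decay50_defined(self) -> bool:
        return np.isfinite(self.decay50)


def normalize(trace: IntensityTrace, n_baseline: int = 10) -> IntensityTrace:
    """Divide a raw trace by its baseline intensity.

    ``I_basal`` is the mean of the ``n_baseline`` frames immediately
    preceding ``stim_frame``.  Normalizing an already-normalized trace is
    the identity (its baseline mean is 1).
    """
    if trace.stim_frame < n_baseline:
        raise PreconditionError(
            f"cell {trace.cell_id!r}: stim_frame={trace.stim_frame} supplies "
            f"fewer than {n_baseline} baseline frames"
        )
    window = slice(trace.stim_frame - n_baseline, trace.stim_frame)
    i_basal = float(np.mean(trace.intensity[window]))
    if i_basal <= 0:
        raise DataError(
            f"cell {trace.cell_id!r}: non-positive baseline intensity "
            f"{i_basal:g}; excluding cell"
        )
    return replace(
        trace,
        intensity=np.asarray(trace.intensity, dtype=float) / i_basal,
        normalized=True,
        i_basal=i_basal,
    )


def _crossing_time(time: np.ndarray, values: np.ndarray, start: int,
                   level: float) -> float:
    """First time at or after index ``start`` where ``values`` crosses down
    through ``level``, linearly interpolated; NaN if it never does."""
    for k in range(start, len(values) - 1):
        v0, v1 = values[k], values[k + 1]
        if v0 >= level > v1:
            frac = (v0 - level) / (v0 - v1)
            return float(time[k] + frac * (time[k + 1] - time[k]))
        if v1 == level:
            return float(time[k + 1])
    return float("nan")


def features(trace: IntensityTrace, decay_mode: str = "mid_level",
             responder_threshold: float = RESPONDER_THRESHOLD,
             check_baseline: bool = True) -> TraceFeatures:
    """Amplitude, 50% decay time and responder flag of a normalized trace.

    The maximum is searched over the post-stimulus frames only.  With
    ``decay_mode="mid_level"`` (default) the decay level is
    ``(amplitude + 1) / 2``, i.e. halfway between maximum and baseline;
    ``"half_max"`` uses ``amplitude / 2``.  ``check_baseline=False`` skips
    the unit-baseline verification (used for model predictions whose fitted
    pulse may start inside the nominal baseline window).
    """
    if not trace.normalized:
        raise PreconditionError(f"cell {trace.cell_id!r}: trace is not normalized")
    baseline = trace.intensity[: trace.stim_frame]
    if check_baseline and abs(float(np.mean(baseline)) - 1.0) > 1e-9:
        raise PreconditionError(
            f"cell {trace.cell_id!r}: baseline mean differs from 1 "
            "(trace not normalized?)"
        )
    post = np.asarray(trace.intensity[trace.stim_frame:], dtype=float)
    k_rel = int(np.argmax(post))
    k_max = trace.stim_frame + k_rel
    amplitude = float(post[k_rel])
    if decay_mode == "mid_level":
        level = (amplitude + 1.0) / 2.0
    elif decay_mode == "half_max":
        level = amplitude / 2.0
    else:
        raise PreconditionError(f"unknown decay_mode {decay_mode!r}")
    t_cross = _crossing_time(np.asarray(trace.time, dtype=float),
                             np.asarray(trace.intensity, dtype=float),
                             k_max, level)
    decay50 = t_cross - float(trace.time[k_max]) if np.isfinite(t_cross) else float("nan")
    return TraceFeatures(
        cell_id=trace.cell_id,
        i_basal=trace.i_basal if trace.i_basal is not None else 1.0,
        amplitude=amplitude,
        decay50=decay50,
        responder=amplitude >= responder_threshold,
        group=trace.group,
    )


def features_table(traces: Iterable[IntensityTrace], **kwargs):
    """Features of many normalized traces as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for tr in traces:
        f = features(tr, **kwargs)
        rows.append({
            "cell_id": f.cell_id, "group": f.group, "i_basal": f.i_basal,
            "amplitude": f.amplitude, "decay50": f.decay50,
            "responder": f.responder,
        })
    return pd.DataFrame(rows)


@dataclass
class CellLayout:
    """Cell outlines and stimulation rectangles in image coordinates (µm).

    Adjacency between two cells means their boundaries come within
    ``adjacency_eps`` µm of each other.
    """

    cells: dict[str, Polygon]
    stim_regions: list[Polygon] = field(default_factory=list)
    adjacency_eps: float = 0.5

    def __post_init__(self) -> None:
        for cid, poly in self.cells.items():
            if poly.area <= 0:
                raise DataError(f"cell {cid!r} has zero area")

    def adjacent(self, a: str, b: str) -> bool:
        return self.cells[a].distance(self.cells[b]) <= self.adjacency_eps

    def to_dict(self) -> dict:
        return {
            "cells": {cid: list(map(list, poly.exterior.coords))
                      for cid, poly in self.cells.items()},
            "stim_regions": [list(map(list, poly.exterior.coords))
                             for poly in self.stim_regions],
            "adjacency_eps": self.adjacency_eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellLayout":
        return cls(
            cells={cid: Polygon(coords) for cid, coords in d["cells"].items()},
            stim_regions=[Polygon(coords) for coords in d["stim_regions"]],
            adjacency_eps=d.get("adjacency_eps", 0.5),
        )


def classify_cells(layout: CellLayout) -> dict[str, str]:
    """Label each cell target / neighbor / other.

    A cell is *target* iff it overlaps a stimulation rectangle with positive
    area, *neighbor* iff it is not a target but adjacent to at least one
    target, and *other* otherwise.  An empty stimulation region labels every
    cell "other".
    """
    labels: dict[str, str] = {}
    targets = []
    for cid, poly in layout.cells.items():
        overlap = any(poly.intersection(region).area > 0
                      for region in layout.stim_regions)
        if overlap:
            labels[cid] = "target"
            targets.append(cid)
    for cid in layout.cells:
        if cid in labels:
            continue
        if any(layout.adjacent(cid, t) for t in targets):
            labels[cid] = "neighbor"
        else:
            labels[cid] = "other"
    return labels


def group_average(traces: Sequence[IntensityTrace], quantiles: int = 4,
                  responders_only: bool = True,
                  responder_threshold: float = RESPONDER_THRESHOLD,
                  ) -> dict[tuple[str, int], IntensityTrace]:
    """Quantile-binned, frame-wise averaged traces per cell group.

    Traces of each group are ranked by amplitude and split into
    ``quantiles`` equally sized bins (ties broken by cell id order); the
    average of a bin is the frame-wise mean of its normalized intensities.
    Groups with fewer responder traces than bins get a reduced bin count
    with a logged warning.
    """
    by_group: dict[str, list[tuple[float, str, IntensityTrace]]] = {}
    for tr in traces:
        if not tr.normalized:
            raise PreconditionError(f"cell {tr.cell_id!r}: trace is not normalized")
        f = features(tr, responder_threshold=responder_threshold)
        if responders_only and not f.responder:
            continue
        by_group.setdefault(tr.group, []).append((f.amplitude, str(tr.cell_id), tr))

    out: dict[tuple[str, int], IntensityTrace] = {}
    for group, members in by_group.items():
        members.sort(key=lambda item: (item[0], item[1]))
        n_bins = min(quantiles, len(members))
        if n_bins < quantiles:
            logger.warning(
                "group %r has only %d traces; reducing to %d amplitude bins",
                group, len(members), n_bins)
        if n_bins == 0:
            continue
        edges = np.linspace(0, len(members), n_bins + 1).round().astype(int)
        for b in range(n_bins):
            chunk = [tr for _, _, tr in members[edges[b]: edges[b + 1]]]
            ref = chunk[0]
            mean_int = np.mean([tr.intensity for tr in chunk], axis=0)
            out[(group, b)] = IntensityTrace(
                cell_id=f"{group}_q{b}",
                frame_index=np.asarray(ref.frame_index),
                time=np.asarray(ref.time),
                intensity=mean_int,
                stim_frame=ref.stim_frame,
                group=group if group in GROUPS else "unlabeled",
                normalized=True,
            )
    return out


def correlate_features(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Returns ``(nan, nan)`` when either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PreconditionError("need at least 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PreconditionError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
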