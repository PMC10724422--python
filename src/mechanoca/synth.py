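"""Synthetic fluorescence recordings with known ground truth.

The generator emulates the statistical structure of a mechanically
stimulated epithelial Ca2+ imaging experiment so that the whole analysis
chain can be exercised and validated without any microscopy data:

* cells tiled on a grid, a thin stimulation rectangle crossing one row;
* target / neighbor / other groups assigned geometrically;
* a responder fraction per group; responders follow the kinetic model with
  the group's stimulus (target cells with Na+ co-influx, neighbor cells
  without, distant cells unstimulated), scaled per cell by a log-normal
  factor to reproduce the cell-to-cell amplitude heterogeneity seen in
  live recordings;
* per-cell log-normal baseline brightness, multiplicative plus additive
  Gaussian noise, and the recording protocol of 10 baseline frames followed
  by 121 post-stimulus frames at 1.23 s.

Everything is deterministic given the seed, and every output row is
accompanied by a ground-truth table (noise-free amplitude, half-decay time
and influx scale) for recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .config import default_parameters, default_stimulus
from .exceptions import ConfigurationError
from .model import ModelParameters, StimulusInflux, simulate_trace
from .traces import CellLayout, classify_cells, features

__all__ = ["SynthConfig", "generate_layout", "generate_traces",
           "generate_particle_tracks"]


@dataclass
class SynthConfig:
    """Configuration of the synthetic experiment.

    The defaults encode the recording protocol (1.23 s frames, 10 baseline
    + 121 post-stimulus frames, a 1.4 x 80 µm stimulation stripe) and
    moderate, explicitly configurable cell-to-cell variability.
    """

    n_cells: int = 200
    frame_interval: float = 1.23
    n_baseline_frames: int = 10
    n_post_frames: int = 121
    # layout: square cells of `cell_size` µm on a grid_rows x grid_cols field
    grid_rows: int = 5
    grid_cols: int = 5
    cell_size: float = 20.0
    stim_rect: tuple[float, float] = (80.0, 1.4)  # width x height, µm
    responder_prob: dict = field(default_factory=lambda: {
        "target": 0.7, "neighbor": 0.5, "other": 0.1})
    #: sigma of the log-normal per-cell scaling of the stimulus intensity
    amplitude_sigma: float = 0.35
    noise_mult_sigma: float = 0.02
    noise_add_sigma: float = 0.01  # in units of I_basal
    #: per-cell baseline brightness I_basal ~ LogNormal(log median, sigma)
    baseline_median: float = 100.0
    baseline_sigma: float = 0.25
    ground_truth_params: ModelParameters | None = None
    target_stimulus: StimulusInflux | None = None
    #: neighbor influx relative to the target influx (gap-junctional entry)
    neighbor_intensity_fraction: float = 0.6
    # particle-track generation
    particle_mean_displacement: float = 41.0  # nm per iteration
    particle_jitter: float = 2.0  # nm
    particle_inscription_time: float = 27.7  # ms
    n_particle_iterations: int = 30
    seed: int = 20231109

    def __post_init__(self) -> None:
        for g, p in self.responder_prob.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"responder_prob[{g!r}] must be in [0, 1]")
        for name in ("amplitude_sigma", "noise_mult_sigma", "noise_add_sigma",
                     "baseline_sigma", "particle_jitter"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.ground_truth_params is None:
            self.ground_truth_params = default_parameters()
        if self.target_stimulus is None:
            stim = default_stimulus()
            self.target_stimulus = dataclasses.replace(
                stim, t_on=self.n_baseline_frames * self.frame_interval)

    @property
    def neighbor_stimulus(self) -> StimulusInflux:
        return dataclasses.replace(
            self.target_stimulus,
            intensity=self.target_stimulus.intensity * self.neighbor_intensity_fraction,
            na_coupled=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ground_truth_params"] = self.ground_truth_params.to_dict()
        d["target_stimulus"] = self.target_stimulus.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if isinstance(d.get("ground_truth_params"), dict):
            d["ground_truth_params"] = ModelParameters.from_dict(d["ground_truth_params"])
        if isinstance(d.get("target_stimulus"), dict):
            d["target_stimulus"] = StimulusInflux.from_dict(d["target_stimulus"])
        if isinstance(d.get("stim_rect"), list):
            d["stim_rect"] = tuple(d["stim_rect"])
        return cls(**d)


def generate_layout(config: SynthConfig) -> CellLayout:
    """One field of non-overlapping square cells with the stimulation stripe
    crossing the middle row (deterministic)."""
    rows, cols, s = config.grid_rows, config.grid_cols, config.cell_size
    if rows * cols < 1:
        raise ConfigurationError("grid must contain at least one cell")
    cells = {}
    for r in range(rows):
        for c in range(cols):
            cells[f"r{r}c{c}"] = box(c * s, r * s, (c + 1) * s, (r + 1) * s)
    w, h = config.stim_rect
    field_w, field_h = cols * s, rows * s
    if w > field_w or h > field_h:
        raise ConfigurationError("stimulation rectangle does not fit the field")
    # stripe through the vertical middle of the central row, flush left
    y_mid = (rows // 2) * s + s / 2
    stim = box(0.0, y_mid - h / 2, w, y_mid + h / 2)
    return CellLayout(cells=cells, stim_regions=[stim])


def _group_stimulus(config: SynthConfig, group: str) -> StimulusInflux | None:
    if group == "target":
        return config.target_stimulus
    if group == "neighbor":
        return config.neighbor_stimulus
    return None


def generate_traces(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic raw trace table plus its ground-truth feature table.

    The field layout is replicated as many times as needed to reach
    ``n_cells`` (each replicate is an independent stimulation experiment).
    Returns ``(traces, truth)`` where ``traces`` has columns
    ``cell_id, frame, time_s, intensity, group, stim_frame`` and ``truth``
    has the per-cell noise-free amplitude, half-decay time and influx
    scale.
    """
    rng = np.random.default_rng(config.seed)
    layout = generate_layout(config)
    labels = classify_cells(layout)
    per_field = len(labels)
    n_fields = math.ceil(config.n_cells / per_field)

    n_frames = config.n_baseline_frames + config.n_post_frames
    stim_frame = config.n_baseline_frames
    frame_times = config.frame_interval * np.arange(n_frames)

    trace_rows = []
    truth_rows = []
    made = 0
    for f_idx in range(n_fields):
        for cid, group in sorted(labels.items()):
            if made >= config.n_cells:
                break
            made += 1
            cell_id = f"f{f_idx}_{cid}"
            responder = bool(rng.random() < config.responder_prob.get(group, 0.0))
            stimulus = _group_stimulus(config, group) if responder else None
            scale = float(rng.lognormal(0.0, config.amplitude_sigma)) \
                if stimulus is not None else 1.0
            if stimulus is not None and stimulus.intensity > 0:
                trace = simulate_trace(
                    config.ground_truth_params, stimulus.scaled(scale),
                    config.frame_interval, config.n_baseline_frames,
                    config.n_post_frames)
                c = trace.intensity
                feats = features(trace)
                true_amp, true_decay = feats.amplitude, feats.decay50
            else:
                c = np.ones(n_frames)
                true_amp, true_decay = 1.0, float("nan")
            i_basal = float(rng.lognormal(np.log(config.baseline_median),
                                          config.baseline_sigma))
            raw = i_basal * c * (1.0 + rng.normal(0.0, config.noise_mult_sigma,
                                                  n_frames))
            raw += i_basal * rng.normal(0.0, config.noise_add_sigma, n_frames)
            trace_rows.append(pd.DataFrame({
                "cell_id": cell_id,
                "frame": np.arange(n_frames),
                "time_s": frame_times,
                "intensity": raw,
                "group": group,
                "stim_frame": stim_frame,
            }))
            truth_rows.append({
                "cell_id": cell_id, "group": group, "responder": responder,
                "jtheta_scale": scale if stimulus is not None else 0.0,
                "true_amplitude": true_amp, "true_decay50": true_decay,
                "i_basal": i_basal,
            })
    traces = pd.concat(trace_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return traces, truth


def generate_particle_tracks(config: SynthConfig) -> pd.DataFrame:
    """Per-iteration particle displacements around the configured mean.

    Emulates the reproducible per-iteration lateral displacement of the
    substrate surface; displacements are clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    disp = rng.normal(config.particle_mean_displacement, config.particle_jitter,
                      config.n_particle_iterations)
    disp = np.clip(disp, 0.0, None)
    return pd.DataFrame({
        "iteration": np.arange(config.n_particle_iterations),
        "displacement_nm": disp,
        "inscription_time_ms": config.particle_inscription_time,
    })
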