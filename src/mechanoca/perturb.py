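"""In-silico perturbations of the calibrated model.

Three computational experiments probe the model mechanisms:

* :func:`influx_sweep` scales the stimulus influx down (loss of
  mechanosensitive channels, e.g. a Piezo1 knockout) while keeping the ER
  amplification untouched, and records how the peak amplitude falls;
* :func:`store_depletion` empties the ER store (``V_cru = 0``,
  a thapsigargin-like intervention) and reports the drop in the
  baseline-referenced amplitude increase;
* :func:`sodium_free` removes the Na+ pathway (no stimulus Na+ influx and
  cytosolic Na+ clamped at rest), mimicking replacement of extracellular
  Na+ with an ion the exchanger cannot use.

:func:`ms_fraction_estimate` inverts the sweep curve at measured wild-type
and knockout amplitude increases to estimate the fraction of influx (and
hence of mechanosensitive channels) lost in the knockout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import PreconditionError, SweepError
from .model import ModelParameters, StimulusInflux, simulate_trace
from .traces import TraceFeatures, features

__all__ = [
    "SweepCurve",
    "influx_sweep",
    "ms_fraction_estimate",
    "store_depletion",
    "sodium_free",
    "ko_amplitude_reduction",
]

#: frame grid used for all perturbation read-outs (recording protocol)
FRAME_INTERVAL = 1.23
N_BASELINE_FRAMES = 10
N_POST_FRAMES = 121


@dataclass(frozen=True)
class SweepCurve:
    """Amplitude increase (peak normalized intensity minus 1) as a function
    of the remaining stimulus-influx fraction."""

    influx_fraction: np.ndarray
    amplitude_increase: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.influx_fraction, dtype=float)
        if np.any(f < 0) or np.any(f > 1) or np.any(np.diff(f) <= 0):
            raise PreconditionError(
                "influx fractions must be sorted and lie in [0, 1]")

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.amplitude_increase) >= -1e-9))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "influx_fraction": self.influx_fraction,
            "amplitude_increase": self.amplitude_increase,
        })


def _amplitude(params: ModelParameters, stimulus: StimulusInflux) -> TraceFeatures:
    trace = simulate_trace(params, stimulus, FRAME_INTERVAL,
                           N_BASELINE_FRAMES, N_POST_FRAMES)
    return features(trace)


def influx_sweep(params: ModelParameters, stimulus: StimulusInflux,
                 fractions: Sequence[float]) -> SweepCurve:
    """Simulate the model at scaled stimulus intensities.

    Each fraction scales only the pulse intensity (the Na+ twin scales with
    it in target cells); every other parameter, including the ER release,
    stays fixed.  The amplitude increase is read off the frame-grid trace
    through the standard feature pipeline.
    """
    fractions = np.asarray(fractions, dtype=float)
    increases = np.empty_like(fractions)
    for i, f in enumerate(fractions):
        try:
            feats = _amplitude(params, stimulus.scaled(float(f)))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise SweepError(f"simulation failed at influx fraction {f:g}: {exc}") from exc
        increases[i] = feats.amplitude - 1.0
    return SweepCurve(influx_fraction=fractions, amplitude_increase=increases)


def ms_fraction_estimate(curve: SweepCurve, wt_increase: float,
                         ko_increase: float) -> float:
    """Percentage decrease in stimulus influx implied by a knockout.

    The sweep curve is rescaled so that fraction 1 maps onto the wild-type
    amplitude increase, then inverted by monotone interpolation at the
    knockout increase.  Returns ``100 * (1 - fraction)``.
    """
    if not curve.is_monotone:
        raise PreconditionError("sweep curve must be monotone to invert")
    if ko_increase > wt_increase:
        raise PreconditionError("ko_increase must not exceed wt_increase")
    if wt_increase <= 0:
        raise PreconditionError("wt_increase must be positive")
    full = curve.amplitude_increase[-1]
    if full <= 0:
        raise SweepError("sweep curve has no response at full influx")
    scaled = curve.amplitude_increase * (wt_increase / full)
    if ko_increase < scaled[0] - 1e-12:
        raise SweepError(
            f"ko_increase {ko_increase:g} lies below the sweep range "
            f"[{scaled[0]:g}, {scaled[-1]:g}]")
    fraction = float(np.interp(ko_increase, scaled, curve.influx_fraction))
    return 100.0 * (1.0 - fraction)


def ko_amplitude_reduction(wt_increase: float,
                           ko_increases: Sequence[float]) -> float:
    """Percentage reduction of the mean knockout amplitude increase relative
    to wild type (increases are amplitude minus baseline)."""
    if wt_increase <= 0:
        raise PreconditionError("wt_increase must be positive")
    return 100.0 * (1.0 - float(np.mean(ko_increases)) / wt_increase)


def store_depletion(params: ModelParameters, stimulus: StimulusInflux) -> float:
    """Percentage drop in amplitude increase when the ER store is emptied.

    Runs paired simulations with ``v_cru`` at its calibrated value and at
    zero (leak re-solved so the depleted model still rests at c = 1) and
    returns ``100 * (1 - increase_depleted / increase_full)``.
    """
    full = _amplitude(params, stimulus).amplitude - 1.0
    depleted_params = params.replace(v_cru=0.0)
    depleted = _amplitude(depleted_params, stimulus).amplitude - 1.0
    if full <= 0:
        raise SweepError("no amplitude increase at full parameters")
    return 100.0 * (1.0 - depleted / full)


def sodium_free(params: ModelParameters,
                stimulus: StimulusInflux) -> TraceFeatures:
    """Features of the response with the Na+ pathway disabled.

    The stimulus Na+ influx is forced to zero and cytosolic Na+ stays
    clamped at its resting value, so the NCX runs at full strength
    throughout.  With ``J_theta* = 0`` the Na+ balance has the exact
    solution ``n(t) = 1``, so the clamp is realized by removing the Na+
    coupling from the stimulus.
    """
    na_free_stim = dataclasses.replace(stimulus, na_coupled=False)
    return _amplitude(params, na_free_stim)
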