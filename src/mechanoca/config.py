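"""Shipped default (calibrated) model configuration.

The default parameter set was calibrated once, with ``scripts/calibrate.py``
(seed 20231109), against the package's reference response summaries: a
target-cell amplitude of ~2.4 with ~71 s half-decay, ~2.0 / ~40 s with the
Na+ pathway disabled, a ~70% loss of the amplitude increase on store
depletion, and a sweep curve retaining over half its response at half
influx.  It is loaded from JSON shipped with the package.
"""

from __future__ import annotations

import json
from importlib import resources

from .model import ModelParameters, StimulusInflux

__all__ = ["default_parameters", "default_stimulus"]


def _load(name: str) -> dict:
    ref = resources.files("mechanoca").joinpath("data", name)
    return json.loads(ref.read_text())


def default_parameters() -> ModelParameters:
    """The shipped calibrated parameter set."""
    return ModelParameters.from_dict(_load("default_params.json"))


def default_stimulus() -> StimulusInflux:
    """The standard target-cell stimulus used with the calibrated set."""
    return StimulusInflux.from_dict(_load("default_stimulus.json"))
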