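import numpy as np
import pytest

from mechanoca import (
    IntensityTrace,
    default_parameters,
    default_stimulus,
    simulate_trace,
)


@pytest.fixture(scope="session")
def params():
    """The shipped calibrated parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def stimulus():
    """The standard target-cell stimulus."""
    return default_stimulus()


@pytest.fixture(scope="session")
def target_trace(params, stimulus):
    """Calibrated target-cell response on the standard frame grid."""
    return simulate_trace(params, stimulus)


def make_trace(intensity, stim_frame=10, frame_interval=1.23, cell_id="c0",
               group="unlabeled", normalized=False):
    intensity = np.asarray(intensity, dtype=float)
    n = intensity.size
    return IntensityTrace(
        cell_id=cell_id,
        frame_index=np.arange(n),
        time=frame_interval * np.arange(n),
        intensity=intensity,
        stim_frame=stim_frame,
        group=group,
        normalized=normalized,
    )


@pytest.fixture
def trace_factory():
    return make_trace
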