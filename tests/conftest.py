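import numpy as np
import pytest

from ifsim import PeriodicBox, SimulationParams, init_system


@pytest.fixture
def params():
    return SimulationParams()


@pytest.fixture
def frozen_params():
    """Parameters with a negligible trial displacement: geometry is exact
    and nothing drifts during sweeps."""
    return SimulationParams(max_displacement_frac=1e-9)


@pytest.fixture
def small_system(params):
    box = PeriodicBox(300.0)
    return init_system(20, box, params, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
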