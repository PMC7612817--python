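import numpy as np
import pytest

from frameloc.models import ModelParams, ModelSpec, get_preset
from frameloc.simulate import simulate_experiment

GRID_ANGLES = [float(a) for a in range(-150, 181, 30)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def world_preset_trials():
    """A moderately sized experiment from the world-centered preset agent."""
    return simulate_experiment({a: 500 for a in GRID_ANGLES},
                               get_preset("world_sim"), seed=1)


@pytest.fixture(scope="session")
def deterministic_world_agent():
    """World-centered responder at the inverse-temperature upper bound."""
    return ModelSpec("world_sinusoid",
                     ModelParams(beta0=0.5, beta1=0.3, beta2=0.0, beta_inv_temp=20.0))
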