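import numpy as np
import pytest
from hypothesis import settings

from ratespike import Network, Neuron

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rate_holder():
    """Neuron that holds a settable rate (r = B) for driving projections."""
    return Neuron(parameters="B = 0.0", equations="r = B")


@pytest.fixture
def decay_neuron():
    return Neuron(parameters="tau = 10.0 : population",
                  equations="tau * dr/dt + r = sum(exc) : init = 1.0")


def make_net(dt=1.0, seed=0):
    return Network(dt=dt, seed=seed)


@pytest.fixture
def net():
    return make_net()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
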