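import numpy as np
import pytest

from weberchoice import NetworkParams
from weberchoice.fixtures import toy_network


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def small_params():
    """A 120-neuron circuit: same dynamics regime, cheap to simulate."""
    return NetworkParams(N=120, n_pool=20, t_stimulus_ms=2000.0)


@pytest.fixture(scope="session")
def default_params():
    return NetworkParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
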