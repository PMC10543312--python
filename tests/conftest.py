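import numpy as np
import pytest

from flexsim import NetworkSpec, NeuronParams, NeuronGroup


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_params():
    """Noise-free neuron parameters."""
    return NeuronParams(sigma=0.0)


@pytest.fixture
def group(quiet_params):
    return NeuronGroup(10, quiet_params, "test")


@pytest.fixture
def small_spec():
    """A reduced network for fast integration tests."""
    return NetworkSpec(n_cna=20, n_da=20, n_gaba=20, n_input=20)
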