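import numpy as np
import pytest

from fluttersim import NeuronParams, PlasticityParams, make_pulse_train


@pytest.fixture(scope="session")
def neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def quiet_neuron() -> NeuronParams:
    """Noise- and jitter-free neuron for deterministic checks."""
    return NeuronParams(sigma_noise=0.0, sigma_jitter=0.0)


@pytest.fixture(scope="session")
def no_plasticity() -> PlasticityParams:
    return PlasticityParams.none()


@pytest.fixture(scope="session")
def train_8hz():
    return make_pulse_train(8.0, 500.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
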