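import numpy as np
import pytest

from bgnet import catalog


@pytest.fixture(scope="session")
def neuron_params():
    return catalog.load_neuron_params()


@pytest.fixture(scope="session")
def synapse_catalog():
    conns, drives = catalog.load_synapse_catalog()
    return {"connections": conns, "drives": drives}


@pytest.fixture(scope="session")
def modulation_table():
    return catalog.load_modulation_table()


@pytest.fixture(scope="session")
def small_config():
    """A small but fully wired network configuration (fan-ins capped where
    the scaled pools are too small)."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return catalog.default_config(2000)


@pytest.fixture(scope="session")
def small_network(small_config):
    import warnings
    from bgnet.network_builder import build_network
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_network(small_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
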