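import numpy as np
import pytest

from ringwm.config import ConnectivityParams, NetworkConfig, ProtocolParams
from ringwm.connectivity import build_profile


@pytest.fixture(scope="session")
def default_profile():
    """Heterogeneous profile at the reference parameters (512 E neurons)."""
    return build_profile(ConnectivityParams())


@pytest.fixture(scope="session")
def default_params():
    return ConnectivityParams()


def uncoupled_config(n_e=4, n_i=1, t_end=500.0, poisson_rate=0.0):
    """A tiny network with all recurrent couplings off (single-cell tests)."""
    cfg = NetworkConfig()
    cfg.connectivity = ConnectivityParams(
        N_E=n_e, N_I=n_i, G_EE_NMDA=0.0, G_EI_NMDA=0.0,
        G_IE_GABA=0.0, G_II_GABA=0.0)
    cfg.synapse.poisson_rate = poisson_rate
    cfg.protocol = ProtocolParams(t_cue_on=0.0, t_cue_off=1.0, t_end=t_end)
    return cfg


@pytest.fixture
def tiny_config():
    return uncoupled_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
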