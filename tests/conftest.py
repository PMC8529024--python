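import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mothal import NetworkParams, build_network

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return NetworkParams()


@pytest.fixture(scope="session")
def network(params):
    return build_network(params, seed=1)


@pytest.fixture(scope="session")
def tiny_pair():
    """One PN + one LN wired to each other (deterministic), for exact
    kernel-accounting checks."""
    from mothal.network import Network
    p = NetworkParams(n_glomeruli=1, n_PN_per_glom=1, n_LN_per_glom=1,
                      p_PN_PN=1.0, p_PN_LN=1.0, p_LN_PN_intra=1.0,
                      p_LN_LN=1.0)
    net = Network(
        params=p, seed=0,
        glom_PN=np.zeros(1, dtype=int), glom_LN=np.zeros(1, dtype=int),
        a_PN_PN=np.zeros((1, 1), dtype=bool),
        a_PN_LN=np.ones((1, 1), dtype=bool),
        a_LN_PN=np.ones((1, 1), dtype=bool),
        a_LN_LN=np.zeros((1, 1), dtype=bool),
        sk_strength=np.array([0.5]))
    return net
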