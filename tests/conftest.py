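import numpy as np
import pytest

import tadcpg as tc
from tadcpg.experiments import simulate_episode
from tadcpg.simulate import InitiationProtocol


@pytest.fixture(scope="session")
def params():
    return tc.default_params()


@pytest.fixture(scope="session")
def rest(params):
    return tc.settle_to_rest(params)


@pytest.fixture(scope="session")
def fig8_weights(params):
    return params.with_weights(w_ampa=10.0, w_nmda=10.0)


@pytest.fixture(scope="session")
def swim60_traj(fig8_weights, rest):
    """3-s episode at w_inh=60 from the weak asymmetric initiation."""
    p = fig8_weights.with_weights(w_inh=60.0)
    proto = InitiationProtocol.from_delta(A=0.01, d=6.0, delta=20.0, t1=10.0)
    return simulate_episode(p, proto, t_end=3000.0, y0=rest)


@pytest.fixture(scope="session")
def sync28_traj(fig8_weights, rest):
    """3-s exactly symmetric episode at w_inh=28 (in-phase manifold)."""
    p = fig8_weights.with_weights(w_inh=28.0)
    proto = InitiationProtocol.from_delta(A=0.01, d=6.0, delta=0.0, t1=10.0)
    return simulate_episode(p, proto, t_end=3000.0, y0=rest)


@pytest.fixture(scope="session")
def sync42_traj(fig8_weights, rest):
    """3-s near-symmetric episode at w_inh=42."""
    p = fig8_weights.with_weights(w_inh=42.0)
    proto = InitiationProtocol.from_delta(A=0.01, d=6.0, delta=1e-4, t1=10.0)
    return simulate_episode(p, proto, t_end=3000.0, y0=rest)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
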