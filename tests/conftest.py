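import numpy as np
import pytest

from popdim.config import NetworkConfig
from popdim.synth import GenerativeFASpec


@pytest.fixture(scope="session")
def three_factor_spec() -> GenerativeFASpec:
    """A strong 3-factor generative model on 80 neurons (~50% shared)."""
    rng = np.random.default_rng(42)
    n, m = 80, 3
    L = rng.standard_normal((n, m))
    psi = np.einsum("ij,ij->i", L, L)  # per-neuron shared == independent
    return GenerativeFASpec(mu=np.full(n, 5.0), L=L, psi=psi)


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    """A very small uncoupled-ish network for fast simulator tests."""
    return NetworkConfig(
        n_excitatory=20,
        n_inhibitory=5,
        p_EE=0.2,
        p_EI=0.5,
        p_IE=0.5,
        p_II=0.5,
    )
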