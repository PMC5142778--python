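"""Random connectivity construction for clustered and non-clustered networks.

Neurons are indexed 0 .. N_E-1 (excitatory) followed by N_E .. N_E+N_I-1
(inhibitory).  The weight matrix is stored sparse with rows = postsynaptic,
columns = presynaptic; every ordered pair is connected independently with
the class-appropriate probability and no self-connections are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .config import ConfigurationError, NetworkConfig


@dataclass
class Network:
    """A realized connectivity draw.

    ``weights[i, j]`` is the synaptic weight from presynaptic neuron ``j``
    onto postsynaptic neuron ``i`` (positive for excitatory ``j``, negative
    for inhibitory ``j``).  ``cluster_label`` holds one integer per
    excitatory neuron (contiguous blocks), or ``None`` for non-clustered
    networks.
    """

    weights: sp.csr_matrix
    config: NetworkConfig
    cluster_label: np.ndarray | None
    seed: int
    population_label: np.ndarray = field(init=False)  # 'E'/'I' per neuron

    def __post_init__(self) -> None:
        cfg = self.config
        self.population_label = np.array(
            ["E"] * cfg.n_excitatory + ["I"] * cfg.n_inhibitory
        )

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def excitatory(self) -> np.ndarray:
        return np.arange(self.config.n_excitatory)

    @property
    def inhibitory(self) -> np.ndarray:
        return np.arange(self.config.n_excitatory, self.config.n_neurons)


def _bernoulli_block(
    rng: np.random.Generator, n_post: int, n_pre: int, p: float
) -> sp.csr_matrix:
    mask = rng.random((n_post, n_pre)) < p
    return sp.csr_matrix(mask)


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Draw one connectivity realization from ``config``.

    Each ordered (post, pre) pair is connected independently with the
    class-appropriate probability; in clustered configs, excitatory pairs
    use ``p_in_EE`` within a cluster and ``p_out_EE`` between clusters,
    with weights ``J_in_EE`` / ``J_out_EE``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ne, ni = config.n_excitatory, config.n_inhibitory

    if config.clustered:
        labels = np.repeat(np.arange(config.n_clusters), config.cluster_size)
        same = labels[:, None] == labels[None, :]
        draw = rng.random((ne, ne))
        p_mat = np.where(same, config.p_in_EE, config.p_out_EE)
        mask = draw < p_mat
        w_ee = np.where(same, config.J_in_EE, config.J_out_EE) * mask
        ee = sp.csr_matrix(w_ee)
    else:
        labels = None
        ee = _bernoulli_block(rng, ne, ne, config.p_EE) * config.J_EE

    ei = _bernoulli_block(rng, ne, ni, config.p_EI) * config.J_EI
    ie = _bernoulli_block(rng, ni, ne, config.p_IE) * config.J_IE
    ii = _bernoulli_block(rng, ni, ni, config.p_II) * config.J_II

    weights = sp.bmat([[ee, ei], [ie, ii]], format="csr")
    weights.setdiag(0.0)
    weights.eliminate_zeros()
    return Network(weights=weights, config=config, cluster_label=labels, seed=seed)


def connection_density(network: Network, post: np.ndarray, pre: np.ndarray) -> float:
    """Empirical connection frequency over the ordered (post, pre) pairs,
    excluding the diagonal."""
    block = network.weights[np.ix_(post, pre)]
    n_pairs = len(post) * len(pre) - len(np.intersect1d(post, pre))
    if n_pairs == 0:
        raise ValueError("no ordered pairs in the requested block")
    return block.nnz / n_pairs
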