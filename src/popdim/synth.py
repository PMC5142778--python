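"""Seed-deterministic synthetic data generators.

Three generators cover the pipeline's test surface without recordings:

* :func:`sample_fa_counts` inverts the factor-analysis model — draw latent
  factors, add independent noise — so estimator recovery can be checked
  against known ground truth;
* :func:`make_invivo_like_params` builds a generative parameter set with
  the statistical signature of cortical spontaneous-activity recordings:
  a dominant same-sign co-fluctuation mode carrying a large share of the
  shared variance, and roughly half of each neuron's count variance
  shared;
* :func:`toy_network_config` shrinks the canonical spiking-network
  configurations to desk scale while preserving the connectivity
  structure analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig, clustered_paper_config, nonclustered_paper_config
from .counts import CountMatrix


@dataclass
class GenerativeFASpec:
    """Ground-truth parameters for sampling from x ~ N(mu, L L^T + Psi).

    With ``poissonize`` on, the Gaussian draw is used as a rate
    (truncated at zero) for a Poisson emission — a crude integer-count
    emulation, documented as such.
    """

    mu: np.ndarray
    L: np.ndarray  # (n, m_true)
    psi: np.ndarray
    poissonize: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.L = np.asarray(self.L, dtype=float).reshape(len(self.mu), -1)
        self.psi = np.asarray(self.psi, dtype=float)
        if np.any(self.psi <= 0):
            raise ValueError("psi must be strictly positive (covariance must be PD)")

    @property
    def n_neurons(self) -> int:
        return len(self.mu)

    @property
    def m_true(self) -> int:
        return self.L.shape[1]

    def covariance(self) -> np.ndarray:
        return self.L @ self.L.T + np.diag(self.psi)


def sample_fa_counts(
    spec: GenerativeFASpec, n_trials: int, seed: int = 0
) -> CountMatrix:
    """Draw ``n_trials`` observations from the generative FA model.

    x = mu + L z + eps with z ~ N(0, I) and eps ~ N(0, Psi); bit-identical
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_trials, spec.m_true))
    eps = rng.standard_normal((n_trials, spec.n_neurons)) * np.sqrt(spec.psi)
    x = spec.mu + z @ spec.L.T + eps
    if spec.poissonize:
        x = rng.poisson(np.maximum(x, 0.0)).astype(np.int64)
    return CountMatrix(counts=x, neuron_ids=np.arange(spec.n_neurons))


def make_invivo_like_params(
    n_neurons: int = 80,
    first_mode_share: float = 0.70,
    overall_psv: float = 51.8,
    m: int = 4,
    mean_rate: float = 4.0,
    total_shared: float | None = None,
    seed: int = 0,
) -> GenerativeFASpec:
    """Generative parameters with the signature of V1 spontaneous activity.

    The first loading column has all-positive entries (|N(1, 0.5^2)|) — a
    population-wide co-fluctuation — and carries ``first_mode_share`` of
    trace(L L^T); the remaining m-1 columns are random directions
    orthogonalized against it, splitting the rest of the shared variance
    in a geometric taper.  Psi is set per neuron so that every neuron's
    percent shared variance equals ``overall_psv`` exactly, hence so does
    the population mean.

    ``overall_psv = 0`` returns an m = 0 (independent-noise) spec.
    """
    if not (0.0 <= overall_psv < 100.0):
        raise ValueError("overall_psv must lie in [0, 100)")
    if not (0.0 < first_mode_share <= 1.0):
        raise ValueError("first_mode_share must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mu = np.full(n_neurons, float(mean_rate))
    if overall_psv == 0.0:
        return GenerativeFASpec(
            mu=mu, L=np.zeros((n_neurons, 0)), psi=np.ones(n_neurons)
        )
    if m < 1:
        raise ValueError("m must be at least 1 for a nonzero shared component")

    if total_shared is None:
        total_shared = float(n_neurons)  # unit shared variance per neuron on average

    u1 = np.abs(rng.normal(1.0, 0.5, size=n_neurons))
    u1 /= np.linalg.norm(u1)
    basis = [u1]
    for _ in range(m - 1):
        v = rng.standard_normal(n_neurons)
        for b in basis:
            v -= (v @ b) * b
        basis.append(v / np.linalg.norm(v))
    u = np.column_stack(basis)

    rest = 1.0 - first_mode_share
    if m > 1:
        taper = 0.5 ** np.arange(m - 1)
        shares = np.concatenate(([first_mode_share], rest * taper / taper.sum()))
    else:
        if rest > 1e-12:
            raise ValueError("m = 1 requires first_mode_share = 1")
        shares = np.array([1.0])
    lam = shares * total_shared
    L = u * np.sqrt(lam)

    shared_k = np.einsum("ij,ij->i", L, L)
    p = overall_psv / 100.0
    psi = shared_k * (1.0 - p) / p
    return GenerativeFASpec(mu=mu, L=L, psi=psi)


def toy_network_config(
    scale: float,
    clustered: bool = True,
    n_clusters: int | None = None,
) -> NetworkConfig:
    """Shrink the canonical network configuration by ``scale``.

    ``scale = 1`` returns the canonical preset verbatim.  For smaller
    scales, population sizes shrink proportionally and, in the clustered
    case, the cluster count and size are both reduced (e.g. scale 0.1
    gives 400 E / 100 I with 10 clusters of 40).  The within/between
    connection-probability ratio p_in/p_out is preserved and p_out is
    re-solved so the pair-count-weighted mean E->E probability stays
    exactly 0.2 at the new geometry.  All synaptic weights are multiplied
    by scale**(-1/4): some compensatory strengthening is needed to keep
    the clustered dynamics metastable at reduced N, but the full
    1/sqrt(scale) balanced-network scaling over-amplifies pairwise
    correlations (which already grow as N shrinks), so the toy networks
    split the difference.  This keeps firing rates plausible and
    preserves the qualitative contrast between the two architectures.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    if scale == 1.0:
        return clustered_paper_config() if clustered else nonclustered_paper_config()

    base = clustered_paper_config() if clustered else nonclustered_paper_config()
    n_e = int(round(base.n_excitatory * scale))
    n_i = int(round(base.n_inhibitory * scale))
    g = scale**-0.25

    kwargs = dict(
        n_excitatory=n_e,
        n_inhibitory=n_i,
        J_EE=base.J_EE * g,
        J_EI=base.J_EI * g,
        J_IE=base.J_IE * g,
        J_II=base.J_II * g,
    )
    if clustered:
        if n_clusters is None:
            # shrink cluster count and size together; round to a divisor of n_E
            target = base.n_clusters * scale**0.7
            divisors = [d for d in range(1, n_e + 1) if n_e % d == 0]
            n_clusters = min(divisors, key=lambda d: abs(d - target))
        if n_e % n_clusters != 0 or n_e // n_clusters < 2:
            raise ValueError(
                f"{n_clusters} clusters do not evenly partition {n_e} excitatory "
                "neurons into clusters of at least 2"
            )
        cluster_size = n_e // n_clusters
        ratio = base.p_in_EE / base.p_out_EE
        f_in = (cluster_size - 1) / (n_e - 1)
        p_out = base.p_EE / (ratio * f_in + (1.0 - f_in))
        j_ratio = base.J_in_EE / base.J_out_EE
        kwargs.update(
            n_clusters=n_clusters,
            cluster_size=cluster_size,
            p_in_EE=ratio * p_out,
            p_out_EE=p_out,
            J_out_EE=base.J_out_EE * g,
            J_in_EE=base.J_out_EE * g * j_ratio,
        )
    else:
        kwargs.update(n_clusters=0)

    cfg = NetworkConfig(**{**base.to_dict(), **kwargs})
    cfg.validate()
    return cfg
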