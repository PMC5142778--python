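"""Prepackaged desk-scale experiments.

The full-size clustered/non-clustered comparison (4000 E neurons, 10^4
simulated seconds, FA at up to 500 neurons) is a multi-hour computation;
these helpers run the same pipeline on the scaled-down networks of
:func:`popdim.synth.toy_network_config`, preserving the qualitative
contrasts: clustered connectivity produces low-dimensional, high-shared-
variance activity detectable from a few hundred 1-s trials, while the
homogeneous network shows no detectable shared structure at the same
sampling.
"""

from __future__ import annotations

import numpy as np

from .counts import CountMatrix, bin_spike_counts
from .fa import cv_select_m, fit_fa, percent_shared_variance, shared_dimensionality
from .network import build_network
from .sampling import nested_neuron_subsets
from .simulate import simulate
from .synth import toy_network_config


def simulate_toy_counts(
    clustered: bool,
    duration: float = 302.0,
    scale: float = 0.1,
    conn_seed: int = 1,
    dyn_seed: int = 2,
) -> CountMatrix:
    """Simulate a toy network and bin it into 1-s trials (burn-in dropped)."""
    cfg = toy_network_config(scale, clustered=clustered)
    net = build_network(cfg, seed=conn_seed)
    rec = simulate(net, duration=duration, seed=dyn_seed)
    return bin_spike_counts(rec)


def excitatory_active_pool(counts: CountMatrix, n_excitatory: int) -> np.ndarray:
    """Excitatory units firing at >= 1 spike/s (the analyzable pool)."""
    pool = counts.active_neurons(min_rate=1.0)
    return pool[pool < n_excitatory]


def fa_metrics_for_subset(
    counts: CountMatrix,
    cols: np.ndarray,
    m_grid: list[int] | None = None,
    seed: int = 0,
) -> tuple[int, int, float]:
    """(m*, d_shared, percent shared variance) for one neuron subset."""
    sub = counts.select_neurons(np.sort(cols))
    if m_grid is not None:
        m_grid = [m for m in m_grid if m <= len(cols) - 1]
    m_star, _ = cv_select_m(sub, m_grid=m_grid, seed=seed)
    model = fit_fa(sub, m_star)
    _, psv = percent_shared_variance(model)
    return m_star, shared_dimensionality(model), psv


def cluster_covariance_contrast(
    counts: CountMatrix, pool: np.ndarray
) -> tuple[float, float]:
    """Mean within-cluster and between-cluster spike-count covariance over
    the given excitatory pool."""
    e = counts.select_neurons(pool)
    if e.cluster_labels is None:
        raise ValueError("counts carry no cluster labels")
    cov = np.cov(np.asarray(e.counts, dtype=float).T)
    same = e.cluster_labels[:, None] == e.cluster_labels[None, :]
    off = ~np.eye(len(pool), dtype=bool)
    return float(cov[same & off].mean()), float(cov[~same & off].mean())


def toy_network_dissociation(
    seed: int = 0,
    duration: float = 302.0,
    n_analysis: int = 40,
    sweep_sizes: tuple[int, ...] = (10, 20, 40),
    n_sweep_repeats: int = 3,
    m_grid: list[int] | None = None,
) -> dict:
    """The clustered vs non-clustered contrast at desk scale.

    Simulates both toy networks once each, then (a) fits FA with CV-selected
    rank to ``n_analysis`` active excitatory neurons of each, (b) contrasts
    within- vs between-cluster covariance in the clustered network, and
    (c) sweeps the clustered network over nested neuron subsets.
    """
    if m_grid is None:
        m_grid = list(range(0, 13))
    rng = np.random.default_rng(seed)
    out: dict = {"seed": seed, "duration": duration}

    for clustered in (True, False):
        key = "clustered" if clustered else "nonclustered"
        counts = simulate_toy_counts(
            clustered,
            duration=duration,
            conn_seed=int(rng.integers(2**31)),
            dyn_seed=int(rng.integers(2**31)),
        )
        n_exc = 400 if counts.n_neurons == 500 else int(0.8 * counts.n_neurons)
        pool = excitatory_active_pool(counts, n_exc)
        cols = rng.choice(pool, size=n_analysis, replace=False)
        m_star, d, psv = fa_metrics_for_subset(
            counts, cols, m_grid=m_grid, seed=seed
        )
        out[key] = {"m_star": m_star, "d_shared": d, "percent_shared": psv}

        if clustered:
            within, between = cluster_covariance_contrast(counts, pool)
            out[key]["within_cluster_cov"] = within
            out[key]["between_cluster_cov"] = between
            sweep = {size: [] for size in sweep_sizes}
            for _ in range(n_sweep_repeats):
                chain = nested_neuron_subsets(
                    pool, list(sweep_sizes), seed=int(rng.integers(2**31))
                )
                for size, cols in zip(sweep_sizes, chain):
                    _, d_s, _ = fa_metrics_for_subset(
                        counts, cols, m_grid=m_grid, seed=seed
                    )
                    sweep[size].append(d_s)
            out[key]["neuron_sweep_d_shared_mean"] = {
                size: float(np.mean(v)) for size, v in sweep.items()
            }
    return out
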