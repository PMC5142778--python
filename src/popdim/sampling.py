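"""Neuron/trial subsampling protocols and scaling curves.

The sweep protocols mirror common practice for population recordings:
neuron sweeps use nested subsets (each sample augments the next smaller
one), repeats use non-overlapping neuron sets crossed with non-overlapping
contiguous trial blocks, and cluster-representation sweeps draw a fixed
number of neurons spread over a chosen number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .fa import cv_select_m, fit_fa, percent_shared_variance, shared_dimensionality


def nested_neuron_subsets(
    pool: np.ndarray, sizes: list[int], seed: int = 0
) -> list[np.ndarray]:
    """Nested random subsets of ``pool``: each set contains the previous
    one, increments drawn uniformly without replacement."""
    pool = np.asarray(pool)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if sizes[-1] > len(pool):
        raise ValueError("largest size exceeds the pool")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pool)
    return [perm[:s].copy() for s in sizes]


def disjoint_sets(
    pool: np.ndarray, n_sets: int, size: int, seed: int = 0
) -> list[np.ndarray]:
    """``n_sets`` pairwise-disjoint uniform subsets of ``pool``."""
    pool = np.asarray(pool)
    if n_sets * size > len(pool):
        raise ValueError(
            f"cannot draw {n_sets} disjoint sets of {size} from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pool)
    return [perm[i * size : (i + 1) * size].copy() for i in range(n_sets)]


def cluster_balanced_sample(
    cluster_labels: np.ndarray,
    n_clusters_represented: int,
    total: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``total`` neurons spread evenly over ``n_clusters_represented``
    clusters: clusters chosen uniformly, then total/N neurons uniformly
    within each.  N must divide ``total``."""
    labels = np.asarray(cluster_labels)
    n = n_clusters_represented
    if n <= 0 or total % n != 0:
        raise ValueError(f"number of represented clusters must divide {total}")
    per = total // n
    clusters = np.unique(labels[labels >= 0])
    if n > len(clusters):
        raise ValueError("more clusters requested than present")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(clusters, size=n, replace=False)
    out = []
    for c in chosen:
        members = np.flatnonzero(labels == c)
        if len(members) < per:
            raise ValueError(f"cluster {c} has fewer than {per} members")
        out.append(rng.choice(members, size=per, replace=False))
    return np.sort(np.concatenate(out))


@dataclass
class ScalingTable:
    """Per-repeat metrics along a subsampling axis, with aggregates."""

    axis: str  # 'neurons' | 'trials' | 'clusters_represented'
    per_repeat: pd.DataFrame  # grid_value, repeat, d_shared, percent_shared
    aggregated: pd.DataFrame  # grid_value, mean/se per metric
    seed: int = 0

    @staticmethod
    def aggregate(per_repeat: pd.DataFrame) -> pd.DataFrame:
        g = per_repeat.groupby("grid_value")
        out = g.agg(
            d_shared_mean=("d_shared", "mean"),
            d_shared_se=("d_shared", "sem"),
            percent_shared_mean=("percent_shared", "mean"),
            percent_shared_se=("percent_shared", "sem"),
            n_repeats=("repeat", "count"),
        ).reset_index()
        return out.fillna({"d_shared_se": 0.0, "percent_shared_se": 0.0})


def _fa_metrics(sub: CountMatrix, fa_opts: dict, seed: int) -> tuple[int, float]:
    m_star, _ = cv_select_m(sub, seed=seed, **fa_opts)
    model = fit_fa(sub, m_star)
    _, psv = percent_shared_variance(model)
    return shared_dimensionality(model), psv


def scaling_experiment(
    counts: CountMatrix,
    axis: str,
    grid: list[int],
    n_neuron_sets: int = 5,
    n_trial_sets: int = 5,
    fixed: int | None = None,
    fa_opts: dict | None = None,
    seed: int = 0,
    neuron_pool: np.ndarray | None = None,
) -> ScalingTable:
    """Sweep d_shared and percent shared variance along neurons or trials.

    ``axis='neurons'``: each of ``n_neuron_sets`` disjoint neuron pools
    provides one nested chain over ``grid``; trials are fixed at ``fixed``
    (default: all available) within each of ``n_trial_sets`` disjoint
    contiguous trial blocks.  ``axis='trials'``: neuron sets of size
    ``fixed`` are disjoint, and each trial block is nested over ``grid``.
    Repeats are the full neuron-set x trial-set crossing.

    ``neuron_pool`` restricts sampling, e.g. to excitatory neurons.
    """
    fa_opts = dict(fa_opts or {})
    grid = sorted(int(g) for g in grid)
    pool = (
        np.arange(counts.n_neurons) if neuron_pool is None else np.asarray(neuron_pool)
    )
    rng = np.random.default_rng(seed)
    rows = []

    if axis == "neurons":
        n_trials_each = counts.n_trials // n_trial_sets if fixed is None else fixed
        if n_trial_sets * n_trials_each > counts.n_trials:
            raise ValueError("not enough trials for the requested trial blocks")
        chains = [
            nested_neuron_subsets(p, grid, seed=int(rng.integers(2**31)))
            for p in disjoint_sets(
                pool, n_neuron_sets, grid[-1], seed=int(rng.integers(2**31))
            )
        ]
        for ti in range(n_trial_sets):
            t0 = ti * n_trials_each
            trial_idx = np.arange(t0, t0 + n_trials_each)
            for ni, chain in enumerate(chains):
                for g, cols in zip(grid, chain):
                    sub = counts.select_neurons(cols).select_trials(trial_idx)
                    d, psv = _fa_metrics(sub, fa_opts, seed)
                    rows.append(
                        {
                            "grid_value": g,
                            "repeat": ni * n_trial_sets + ti,
                            "neuron_set": ni,
                            "trial_set": ti,
                            "d_shared": d,
                            "percent_shared": psv,
                        }
                    )
    elif axis == "trials":
        if fixed is None:
            raise ValueError("axis='trials' needs the fixed neuron count")
        if n_trial_sets * grid[-1] > counts.n_trials:
            raise ValueError("not enough trials for the requested grid")
        neuron_sets = disjoint_sets(
            pool, n_neuron_sets, fixed, seed=int(rng.integers(2**31))
        )
        for ti in range(n_trial_sets):
            t0 = ti * grid[-1]
            for ni, cols in enumerate(neuron_sets):
                for g in grid:
                    trial_idx = np.arange(t0, t0 + g)
                    sub = counts.select_neurons(cols).select_trials(trial_idx)
                    d, psv = _fa_metrics(sub, fa_opts, seed)
                    rows.append(
                        {
                            "grid_value": g,
                            "repeat": ni * n_trial_sets + ti,
                            "neuron_set": ni,
                            "trial_set": ti,
                            "d_shared": d,
                            "percent_shared": psv,
                        }
                    )
    elif axis == "clusters_represented":
        if counts.cluster_labels is None:
            raise ValueError("cluster-representation sweep needs cluster labels")
        total = fixed if fixed is not None else 50
        n_trials_each = counts.n_trials // n_trial_sets
        for ti in range(n_trial_sets):
            t0 = ti * n_trials_each
            trial_idx = np.arange(t0, t0 + n_trials_each)
            for ni in range(n_neuron_sets):
                for g in grid:
                    cols = cluster_balanced_sample(
                        counts.cluster_labels,
                        g,
                        total=total,
                        seed=int(rng.integers(2**31)),
                    )
                    sub = counts.select_neurons(cols).select_trials(trial_idx)
                    d, psv = _fa_metrics(sub, fa_opts, seed)
                    rows.append(
                        {
                            "grid_value": g,
                            "repeat": ni * n_trial_sets + ti,
                            "neuron_set": ni,
                            "trial_set": ti,
                            "d_shared": d,
                            "percent_shared": psv,
                        }
                    )
    else:
        raise ValueError(f"unknown axis {axis!r}")

    per_repeat = pd.DataFrame(rows)
    return ScalingTable(
        axis=axis,
        per_repeat=per_repeat,
        aggregated=ScalingTable.aggregate(per_repeat),
        seed=seed,
    )


def count_autocorrelation(
    counts: CountMatrix, max_lag: int = 20
) -> tuple[pd.DataFrame, np.ndarray]:
    """Biased per-neuron autocorrelation of the trial-ordered count series.

    Lag 0 is exactly 1.  Returns (summary DataFrame with population mean
    and SE per lag, per-neuron lag x neuron matrix).  Constant-count
    neurons are excluded from the population mean (NaN in the matrix).
    """
    x = np.asarray(counts.counts, dtype=float)
    t, n = x.shape
    if max_lag >= t:
        raise ValueError("max_lag must be below the number of trials")
    xc = x - x.mean(axis=0)
    var = (xc**2).sum(axis=0)
    ok = var > 0
    acf = np.full((max_lag + 1, n), np.nan)
    acf[0, ok] = 1.0
    for lag in range(1, max_lag + 1):
        num = (xc[:-lag] * xc[lag:]).sum(axis=0)
        acf[lag, ok] = num[ok] / var[ok]
    valid = acf[:, ok]
    mean = valid.mean(axis=1)
    se = valid.std(axis=1, ddof=1) / np.sqrt(valid.shape[1])
    summary = pd.DataFrame(
        {"lag": np.arange(max_lag + 1), "mean": mean, "se": se}
    )
    return summary, acf


def trial_spacing_check(
    counts: CountMatrix,
    n_trials: int = 400,
    spacings: tuple[int, ...] = (0, 1, 2),
    fa_opts: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """FA metrics under adjacent, skip-k, and random trial samplings.

    If consecutive 1-s trials were autocorrelated, spacing them out would
    change the metrics; indistinguishable results across spacings support
    treating trials as exchangeable.
    """
    fa_opts = dict(fa_opts or {})
    rng = np.random.default_rng(seed)
    rows = []
    for sp in spacings:
        step = sp + 1
        idx = np.arange(0, n_trials * step, step)
        if idx[-1] >= counts.n_trials:
            raise ValueError(f"not enough trials for spacing {sp}")
        d, psv = _fa_metrics(counts.select_trials(idx), fa_opts, seed)
        rows.append(
            {"sampling": f"skip_{sp}s", "d_shared": d, "percent_shared": psv}
        )
    idx = np.sort(rng.choice(counts.n_trials, size=n_trials, replace=False))
    d, psv = _fa_metrics(counts.select_trials(idx), fa_opts, seed)
    rows.append({"sampling": "random", "d_shared": d, "percent_shared": psv})
    return pd.DataFrame(rows)
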