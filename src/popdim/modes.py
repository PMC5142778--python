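"""Comparing dominant modes of shared variability across neuron counts.

Mode vectors from fits with different neuron counts live in different
ambient spaces, so they are compared after restriction to a common neuron
set: take the rows of L for the common neurons, eigendecompose the
restricted L L^T, and keep the top modes.  Subspace similarity is then
measured by principal angles (arccos of the singular values of Q_A^T Q_B,
both bases orthonormalized), with a Monte-Carlo baseline of angles between
independent random subspaces for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .fa import (
    FAModel,
    cv_select_m,
    fit_fa,
    per_mode_percent_shared_variance,
    shared_spectrum,
)
from .sampling import nested_neuron_subsets


@dataclass
class ModeBasis:
    """Top modes of a (possibly row-restricted) shared covariance."""

    neuron_index: np.ndarray  # ambient neuron ids (the common set)
    basis: np.ndarray  # (len(neuron_index), k), orthonormal columns
    eigenvalues: np.ndarray | None = None
    source: str = ""

    @property
    def k(self) -> int:
        return self.basis.shape[1]


@dataclass
class AngleSet:
    """Principal angles in degrees, ascending."""

    degrees: np.ndarray
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None


def restricted_modes(
    model: FAModel, common_neurons: np.ndarray, k: int = 5
) -> ModeBasis:
    """Top-k eigenvectors of the shared covariance restricted to
    ``common_neurons`` (positional column indices into the model).

    If the restricted covariance has rank below k, the available modes are
    returned with a warning.
    """
    common = np.asarray(common_neurons)
    if np.any(common < 0) or np.any(common >= model.n_neurons):
        raise IndexError("common_neurons out of range for this model")
    if k > len(common):
        raise ValueError("k cannot exceed the size of the common set")
    l_sub = model.L[common, :]
    u, sv, _ = np.linalg.svd(l_sub, full_matrices=False)
    evals = sv**2
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    if rank < k:
        warnings.warn(
            f"restricted shared covariance has rank {rank} < k = {k}; "
            "returning the available modes",
            stacklevel=2,
        )
        k = rank
    return ModeBasis(
        neuron_index=common,
        basis=u[:, :k],
        eigenvalues=evals[:k],
        source=f"restricted from {model.n_neurons}-neuron model",
    )


def _orthonormalize(basis: np.ndarray) -> np.ndarray:
    # QR with column pivoting guards against rank-deficient inputs
    from scipy.linalg import qr

    q, r, _ = qr(basis, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r[0, 0]) * 1e-12))
    return q[:, :rank]


def principal_angles(a: ModeBasis, b: ModeBasis) -> AngleSet:
    """Principal angles between the spans of two mode bases (degrees,
    ascending).  Both bases must refer to the same ambient neuron set."""
    if len(a.neuron_index) != len(b.neuron_index) or np.any(
        a.neuron_index != b.neuron_index
    ):
        raise ValueError("mode bases refer to different ambient neuron sets")
    qa = _orthonormalize(a.basis)
    qb = _orthonormalize(b.basis)
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(sv, -1.0, 1.0)))
    return AngleSet(degrees=np.sort(angles))


def random_angle_baseline(
    ambient: int = 20, k: int = 5, reps: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo principal angles between two independent k-dimensional
    subspaces of R^ambient drawn from the rotation-invariant ensemble
    (orthonormalized Gaussian matrices).  Returns (mean, sd) per angle
    index, degrees."""
    if k > ambient:
        raise ValueError("k cannot exceed the ambient dimension")
    rng = np.random.default_rng(seed)
    idx = np.arange(ambient)
    out = np.empty((reps, k))
    for r in range(reps):
        qa = np.linalg.qr(rng.standard_normal((ambient, k)))[0]
        qb = np.linalg.qr(rng.standard_normal((ambient, k)))[0]
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        out[r] = np.sort(np.degrees(np.arccos(np.clip(sv, -1.0, 1.0))))
    return out.mean(axis=0), out.std(axis=0, ddof=1)


def mode_stability_experiment(
    counts: CountMatrix,
    subset_sizes: list[int],
    reference_size: int,
    common_size: int = 20,
    k: int = 5,
    fa_opts: dict | None = None,
    seed: int = 0,
    baseline_reps: int = 1000,
) -> dict:
    """How stable are the dominant modes as the neuron count grows?

    Nested neuron subsets of the requested sizes (each containing the
    smaller ones, all contained in a reference set) are drawn from the
    count matrix; FA is fit per subset with cross-validated rank; modes
    are restricted to the common core (the first ``common_size`` neurons
    of the smallest subset) and compared to the reference fit by principal
    angles.

    Returns a dict with keys ``angles`` (DataFrame: subset_size,
    angle_index, degrees), ``baseline_mean``/``baseline_sd``,
    ``per_mode_psv`` (per-mode percent shared variance for the smallest
    and reference fits), and ``models``.
    """
    fa_opts = dict(fa_opts or {})
    sizes = sorted(subset_sizes)
    if sizes[0] < common_size:
        raise ValueError("smallest subset must contain the common core")
    if reference_size < sizes[-1]:
        raise ValueError("reference size must be at least the largest subset")
    pool = np.arange(counts.n_neurons)
    chain = nested_neuron_subsets(pool, sizes + [reference_size], seed=seed)
    common = chain[0][:common_size]

    def _fit(cols: np.ndarray) -> FAModel:
        sub = counts.select_neurons(cols)
        m_star, _ = cv_select_m(sub, seed=seed, **fa_opts)
        return fit_fa(sub, m_star)

    models = {}
    bases = {}
    for size, cols in zip(sizes + [reference_size], chain):
        model = _fit(cols)
        models[size] = (cols, model)
        # positions of the common neurons within this subset's column order
        pos = np.array([int(np.flatnonzero(cols == c)[0]) for c in common])
        local = restricted_modes(model, pos, k=min(k, model.m) if model.m else 0)
        bases[size] = ModeBasis(
            neuron_index=common, basis=local.basis, eigenvalues=local.eigenvalues
        )

    ref_basis = bases[reference_size]
    rows = []
    for size in sizes:
        if bases[size].k == 0 or ref_basis.k == 0:
            continue
        ang = principal_angles(bases[size], ref_basis)
        for i, deg in enumerate(ang.degrees):
            rows.append({"subset_size": size, "angle_index": i + 1, "degrees": deg})
    angles = pd.DataFrame(rows)

    base_mean, base_sd = random_angle_baseline(
        ambient=common_size, k=k, reps=baseline_reps, seed=seed
    )
    per_mode = {
        size: per_mode_percent_shared_variance(models[size][1])
        for size in (sizes[0], reference_size)
    }
    return {
        "angles": angles,
        "baseline_mean": base_mean,
        "baseline_sd": base_sd,
        "per_mode_psv": per_mode,
        "models": models,
        "common_neurons": common,
    }
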