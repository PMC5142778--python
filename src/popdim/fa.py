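"""Factor analysis of spike counts and the derived shared-variance metrics.

The model treats the spike-count vector x (one trial) as

    x ~ N(mu, L L^T + Psi),

with L an n x m loading matrix and Psi a diagonal matrix of independent
variances: L L^T is the covariance shared across neurons, Psi the part
private to each neuron.  Parameters are fit by expectation-maximization on
the sufficient statistics (sample mean and covariance), the latent
dimensionality m is chosen by cross-validated held-out likelihood, and the
population metrics are read off the eigenstructure of L L^T:

* shared dimensionality ``d_shared``: the number of leading eigenmodes
  needed to capture 95% of trace(L L^T);
* percent shared variance of neuron k: 100 * (L L^T)_kk / ((L L^T)_kk + Psi_k),
  averaged over neurons for the population value;
* per-mode fractions: 100 * lambda_i / sum_j lambda_j of the shared
  variance, and the per-mode split of percent shared variance
  100 * lambda_i u_ik^2 / ((L L^T)_kk + Psi_k) averaged over k, which sums
  over modes to the per-neuron percent shared variance exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .counts import CountMatrix

_PSI_FLOOR_FRAC = 1e-6  # floor on Psi, relative to each neuron's sample variance


def _as_matrix(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return np.asarray(counts.counts, dtype=float)
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a trials x neurons matrix")
    return x


@dataclass
class FAModel:
    """A fitted factor-analysis model."""

    mu: np.ndarray  # (n,)
    L: np.ndarray  # (n, m)
    psi: np.ndarray  # (n,) diagonal independent variances
    m: int
    n_iter: int = 0
    loglik: float = np.nan  # final training log-likelihood (nats, summed)
    converged: bool = True
    loglik_trace: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.mu)

    def shared_covariance(self) -> np.ndarray:
        return self.L @ self.L.T

    def total_covariance(self) -> np.ndarray:
        return self.shared_covariance() + np.diag(self.psi)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "L": self.L.tolist(),
            "psi": self.psi.tolist(),
            "m": int(self.m),
            "n_iter": int(self.n_iter),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FAModel":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            L=np.asarray(d["L"], dtype=float).reshape(len(d["mu"]), d["m"]),
            psi=np.asarray(d["psi"], dtype=float),
            m=int(d["m"]),
            n_iter=int(d.get("n_iter", 0)),
            loglik=float(d.get("loglik", np.nan)),
            converged=bool(d.get("converged", True)),
        )


@dataclass
class SharedSpectrum:
    """Eigenstructure of the shared covariance L L^T."""

    eigenvalues: np.ndarray  # descending, length m
    modes: np.ndarray  # (n, m), orthonormal columns

    @property
    def m(self) -> int:
        return len(self.eigenvalues)

    @property
    def total_shared(self) -> float:
        return float(self.eigenvalues.sum())


def _gauss_loglik_stats(
    L: np.ndarray, psi: np.ndarray, s_mu: np.ndarray, n_trials: int
) -> float:
    """Sum over trials of the N(mu, LL^T+Psi) log density, given the
    second-moment matrix about the model mean, S_mu = mean_t (x_t-mu)(x_t-mu)^T.

    Uses the matrix inversion and determinant lemmas so only an m x m
    system is solved.
    """
    p = len(psi)
    inv_psi = 1.0 / psi
    if L.size == 0:
        logdet = float(np.sum(np.log(psi)))
        quad = float(np.sum(inv_psi * np.diag(s_mu)))
    else:
        lt_ipsi = L.T * inv_psi  # (m, n)
        cap = np.eye(L.shape[1]) + lt_ipsi @ L  # I + L^T Psi^-1 L
        sign, logdet_cap = np.linalg.slogdet(cap)
        if sign <= 0:
            raise np.linalg.LinAlgError("model covariance is not positive definite")
        logdet = logdet_cap + float(np.sum(np.log(psi)))
        # Sigma^-1 = Psi^-1 - Psi^-1 L cap^-1 L^T Psi^-1
        quad = float(np.sum(inv_psi * np.diag(s_mu)))
        inner = lt_ipsi @ s_mu @ lt_ipsi.T
        quad -= float(np.trace(np.linalg.solve(cap, inner)))
    return -0.5 * n_trials * (p * np.log(2.0 * np.pi) + logdet + quad)


def log_likelihood(counts, model: FAModel) -> float:
    """Exact Gaussian log-likelihood of ``counts`` under ``model`` (nats,
    summed over trials)."""
    x = _as_matrix(counts)
    if x.shape[1] != model.n_neurons:
        raise ValueError("neuron dimension mismatch between data and model")
    d = x - model.mu
    s_mu = (d.T @ d) / x.shape[0]
    return _gauss_loglik_stats(model.L, model.psi, s_mu, x.shape[0])


def fit_fa(
    counts,
    m: int,
    tol: float = 1e-8,
    max_iter: int = 3000,
    seed: int | None = None,
) -> FAModel:
    """Fit the m-factor model by EM.

    The fit is deterministic given the data: L is initialized from the
    top-m principal directions of the sample covariance (scaled by the
    square root of each eigenvalue's excess over the mean variance) and
    Psi from the sample variances, so ``seed`` is accepted for interface
    uniformity but unused.  The training log-likelihood is non-decreasing
    across iterations; Psi is floored at a small fraction of each neuron's
    sample variance to prevent Heywood collapse.

    For ``m = 0`` the model is pure independent noise: L empty and Psi the
    maximum-likelihood sample variances.
    """
    x = _as_matrix(counts)
    n_trials, p = x.shape
    if m < 0:
        raise ValueError("m must be non-negative")
    if m > p - 1:
        raise ValueError(f"m ({m}) must be at most n_neurons - 1 ({p - 1})")
    if n_trials <= p:
        warnings.warn(
            f"only {n_trials} trials for {p} neurons; FA estimates may be poor",
            stacklevel=2,
        )

    mu = x.mean(axis=0)
    d = x - mu
    s = (d.T @ d) / n_trials  # ML covariance
    var = np.diag(s).copy()
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(
            f"zero-variance neurons at columns {bad.tolist()}: drop or jitter them"
        )
    floor = _PSI_FLOOR_FRAC * var

    if m == 0:
        ll = _gauss_loglik_stats(np.zeros((p, 0)), var, s, n_trials)
        return FAModel(
            mu=mu, L=np.zeros((p, 0)), psi=var, m=0, n_iter=0, loglik=ll,
            loglik_trace=np.array([ll]),
        )

    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = var.copy()
    excess = np.maximum(evals[:m] - psi.mean(), 1e-3 * psi.mean())
    L = evecs[:, :m] * np.sqrt(excess)

    trace = np.empty(max_iter)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(max_iter):
        inv_psi = 1.0 / psi
        lt_ipsi = L.T * inv_psi
        cap = np.eye(m) + lt_ipsi @ L
        beta = np.linalg.solve(cap, lt_ipsi)  # (m, n) = L^T Sigma^-1
        s_beta_t = s @ beta.T  # (n, m)
        # E[z z^T] aggregated over trials (per-trial average)
        ezz = np.eye(m) - beta @ L + beta @ s_beta_t
        L = np.linalg.solve(ezz.T, s_beta_t.T).T
        psi = np.maximum(np.diag(s) - np.einsum("ij,ij->i", L, s_beta_t), floor)

        ll = _gauss_loglik_stats(L, psi, s, n_trials)
        trace[it] = ll
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll

    return FAModel(
        mu=mu,
        L=L,
        psi=psi,
        m=m,
        n_iter=it + 1,
        loglik=float(trace[it]),
        converged=converged,
        loglik_trace=trace[: it + 1].copy(),
    )


def default_m_grid(n_neurons: int, max_m: int | None = None) -> list[int]:
    """Coarse candidate grid: unit steps to 10, then wider steps."""
    if max_m is None:
        max_m = min(n_neurons - 1, 50)
    max_m = min(max_m, n_neurons - 1)
    grid = list(range(0, min(10, max_m) + 1))
    grid += list(range(12, max_m + 1, 3))
    return sorted(set(grid))


def _cv_score(x, m_values, folds, rng, tol, max_iter):
    n_trials = x.shape[0]
    perm = rng.permutation(n_trials)
    fold_idx = np.array_split(perm, folds)
    scores = {m: 0.0 for m in m_values}
    for held in fold_idx:
        train_mask = np.ones(n_trials, dtype=bool)
        train_mask[held] = False
        x_train, x_test = x[train_mask], x[held]
        for m in m_values:
            model = fit_fa(x_train, m, tol=tol, max_iter=max_iter)
            scores[m] += log_likelihood(x_test, model)
    # mean held-out log-likelihood per trial, comparable across grids
    return {m: s / n_trials for m, s in scores.items()}


def cv_select_m(
    counts,
    m_grid: list[int] | None = None,
    folds: int = 4,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    refine: bool = True,
) -> tuple[int, dict[int, float]]:
    """Select the FA rank m by cross-validated likelihood.

    Trials are partitioned at random (seeded) into ``folds`` folds; for
    each candidate m the model is fit on the training folds and scored on
    the held-out fold.  Returns the argmax of the mean held-out
    log-likelihood (ties broken toward the smallest m) and the per-m
    scores.  With ``m_grid=None`` a coarse grid is evaluated first and
    unit steps around its argmax are then filled in.
    """
    x = _as_matrix(counts)
    n_trials, p = x.shape
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if n_trials < folds:
        raise ValueError(f"need at least {folds} trials for {folds}-fold CV")

    auto = m_grid is None
    if auto:
        m_grid = default_m_grid(p)
    else:
        m_grid = sorted(set(int(m) for m in m_grid))
        if any(m < 0 or m > p - 1 for m in m_grid):
            raise ValueError("m_grid entries must lie in [0, n_neurons - 1]")
        if 0 not in m_grid:
            raise ValueError("m_grid must include 0")

    # a single fold split is reused for every m so scores are comparable
    rng_state = np.random.default_rng(seed)
    scores = _cv_score(x, m_grid, folds, rng_state, tol, max_iter)
    best = min(
        scores, key=lambda m: (-scores[m], m)
    )  # max score, ties -> smallest m

    if auto and refine:
        lo = max(0, best - 2)
        hi = min(p - 1, best + 2)
        extra = [m for m in range(lo, hi + 1) if m not in scores]
        if extra:
            rng_state = np.random.default_rng(seed)  # identical folds
            scores.update(_cv_score(x, extra, folds, rng_state, tol, max_iter))
            best = min(scores, key=lambda m: (-scores[m], m))
    return best, scores


def shared_spectrum(model: FAModel) -> SharedSpectrum:
    """Eigen-decomposition of the shared covariance L L^T.

    Computed from the SVD of L for stability; eigenvector signs follow the
    convention that each mode's largest-magnitude entry is positive.
    """
    if model.m == 0:
        return SharedSpectrum(
            eigenvalues=np.empty(0), modes=np.empty((model.n_neurons, 0))
        )
    u, sv, _ = np.linalg.svd(model.L, full_matrices=False)
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    return SharedSpectrum(eigenvalues=sv**2, modes=u * flip)


def shared_dimensionality(
    model_or_spectrum: FAModel | SharedSpectrum, frac: float = 0.95
) -> int:
    """Number of leading modes needed to explain ``frac`` of the shared
    variance (d_shared).  Zero for an m = 0 model."""
    spec = (
        model_or_spectrum
        if isinstance(model_or_spectrum, SharedSpectrum)
        else shared_spectrum(model_or_spectrum)
    )
    if spec.m == 0 or spec.total_shared <= 0:
        return 0
    cum = np.cumsum(spec.eigenvalues)
    return int(np.searchsorted(cum, frac * cum[-1] - 1e-12) + 1)


def percent_shared_variance(model: FAModel) -> tuple[np.ndarray, float]:
    """Per-neuron percent shared variance and its unweighted population mean.

    Neuron k's value is 100 * (L L^T)_kk / ((L L^T)_kk + Psi_k).
    """
    shared = np.einsum("ij,ij->i", model.L, model.L) if model.m else np.zeros(
        model.n_neurons
    )
    per_neuron = 100.0 * shared / (shared + model.psi)
    return per_neuron, float(per_neuron.mean())


def mode_variance_fractions(spectrum: SharedSpectrum) -> np.ndarray:
    """Percent of shared variance explained by each mode (descending);
    empty for m = 0."""
    if spectrum.m == 0:
        return np.empty(0)
    return 100.0 * spectrum.eigenvalues / spectrum.total_shared


def per_mode_percent_shared_variance(
    model: FAModel, spectrum: SharedSpectrum | None = None
) -> np.ndarray:
    """Percent shared variance along each mode, averaged over neurons.

    Mode i's entry is mean_k 100 * lambda_i u_ik^2 / ((L L^T)_kk + Psi_k);
    summing over modes recovers the population percent shared variance.
    """
    if spectrum is None:
        spectrum = shared_spectrum(model)
    if spectrum.m == 0:
        return np.empty(0)
    shared = np.einsum("ij,ij->i", model.L, model.L)
    total = shared + model.psi  # (n,)
    contrib = spectrum.eigenvalues[None, :] * spectrum.modes**2  # (n, m)
    return (100.0 * contrib / total[:, None]).mean(axis=0)
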