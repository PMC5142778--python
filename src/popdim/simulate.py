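"""Leaky integrate-and-fire dynamics with difference-of-exponentials synapses.

Each neuron obeys  dV/dt = (mu - V)/tau + I_syn  with threshold 1, reset 0
and a 5 ms absolute refractory period.  A presynaptic spike at t0 adds
J * F(t - t0) to the postsynaptic drive, with

    F(t) = (exp(-t/tau2) - exp(-t/tau1)) / (tau2 - tau1),

which integrates to 1 for any valid pair of time constants, so J is the
total charge delivered per spike.  The filter is realized exactly as the
difference of two first-order states per (neuron x presynaptic class),
decayed by exact exponential factors every step; the membrane leak uses
exponential Euler with forward accumulation of the synaptic drive.

The inner loop is compiled with numba; identical (network, seed) inputs
produce bit-identical spike trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import NetworkConfig
from .network import Network


class SimulationError(RuntimeError):
    """Raised when the integration produces non-finite state."""


def synaptic_filter(t: np.ndarray | float, tau1: float, tau2: float):
    """Difference-of-exponentials synaptic kernel, units 1/ms.

    ``F(t) = (exp(-t/tau2) - exp(-t/tau1)) / (tau2 - tau1)`` for ``t >= 0``;
    zero at ``t = 0`` and of unit integral.
    """
    if tau1 >= tau2:
        raise ValueError(f"tau1 ({tau1}) must be smaller than tau2 ({tau2})")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("filter is causal: t must be non-negative")
    return (np.exp(-t / tau2) - np.exp(-t / tau1)) / (tau2 - tau1)


@dataclass
class SpikeRecord:
    """Time-sorted spike events from one simulation run.

    ``neuron`` and ``time`` are parallel arrays; times are in seconds within
    ``[0, duration)``.
    """

    neuron: np.ndarray  # int64
    time: np.ndarray  # float64, seconds, sorted
    duration: float  # seconds
    config: NetworkConfig | None = None

    @property
    def n_events(self) -> int:
        return len(self.time)

    def rates(self, n_neurons: int, t_start: float = 0.0) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over [t_start, duration)."""
        span = self.duration - t_start
        keep = self.time >= t_start
        return np.bincount(self.neuron[keep], minlength=n_neurons) / span


@njit(cache=True)
def _run_lif(
    n_steps,
    dt,
    v,
    mu,
    alpha_m,  # exp(-dt/tau_m) per neuron
    v_th,
    v_re,
    ref_steps,
    dec_a_e,
    dec_a_i,
    dec_b,  # decay factors for the three distinct synaptic time constants
    amp_e,
    amp_i,  # 1/(tau2 - tau1) per presynaptic class
    indptr,
    indices,
    wdata,  # out-adjacency (CSR over presynaptic neurons)
    n_exc,
):
    n = v.shape[0]
    a_e = np.zeros(n)
    b_e = np.zeros(n)
    a_i = np.zeros(n)
    b_i = np.zeros(n)
    ref_until = np.full(n, -1, dtype=np.int64)

    cap = max(1024, n * 64)
    sp_n = np.empty(cap, dtype=np.int64)
    sp_t = np.empty(cap, dtype=np.float64)
    count = 0

    spiked = np.empty(n, dtype=np.int64)
    for step in range(n_steps):
        n_spiked = 0
        for i in range(n):
            if step < ref_until[i]:
                v[i] = v_re
                continue
            syn = (a_e[i] - b_e[i]) + (a_i[i] - b_i[i])
            v[i] = mu[i] + (v[i] - mu[i]) * alpha_m[i] + dt * syn
            if not np.isfinite(v[i]):
                return sp_n[:count], sp_t[:count], i, step
            if v[i] >= v_th:
                v[i] = v_re
                ref_until[i] = step + 1 + ref_steps
                spiked[n_spiked] = i
                n_spiked += 1

        # decay synaptic states to the start of the next step
        for i in range(n):
            a_e[i] *= dec_a_e
            b_e[i] *= dec_b
            a_i[i] *= dec_a_i
            b_i[i] *= dec_b

        # deliver this step's spikes (their filter value at the next step
        # start is F(0) = 0 by construction of the two-state difference)
        for k in range(n_spiked):
            j = spiked[k]
            if count + 1 > cap:
                new_cap = cap * 2
                new_n = np.empty(new_cap, dtype=np.int64)
                new_t = np.empty(new_cap, dtype=np.float64)
                new_n[:count] = sp_n[:count]
                new_t[:count] = sp_t[:count]
                sp_n = new_n
                sp_t = new_t
                cap = new_cap
            sp_n[count] = j
            sp_t[count] = step * dt
            count += 1
            exc = j < n_exc
            amp = amp_e if exc else amp_i
            for p in range(indptr[j], indptr[j + 1]):
                i = indices[p]
                w = wdata[p] * amp
                if exc:
                    a_e[i] += w
                    b_e[i] += w
                else:
                    a_i[i] += w
                    b_i[i] += w

    return sp_n[:count], sp_t[:count], -1, -1


def simulate(
    network: Network,
    duration: float,
    seed: int,
    config: NetworkConfig | None = None,
) -> SpikeRecord:
    """Integrate the network for ``duration`` seconds.

    ``seed`` controls the dynamics draw only: the per-neuron constant bias
    (uniform within the population's bias range) and the initial voltages
    (uniform on [v_reset, v_threshold)).  Connectivity randomness lives in
    :func:`popdim.network.build_network`.
    """
    cfg = config if config is not None else network.config
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = cfg.dt
    ref_steps = cfg.refractory / dt
    if abs(ref_steps - round(ref_steps)) > 1e-9:
        raise ValueError("dt must divide the refractory period evenly")
    ref_steps = int(round(ref_steps))

    n, ne = cfg.n_neurons, cfg.n_excitatory
    rng = np.random.default_rng(seed)
    mu = np.empty(n)
    mu[:ne] = rng.uniform(*cfg.bias_range_e, size=ne)
    mu[ne:] = rng.uniform(*cfg.bias_range_i, size=n - ne)
    v0 = rng.uniform(cfg.v_reset, cfg.v_threshold, size=n)

    tau_m = np.where(np.arange(n) < ne, cfg.tau_m_e, cfg.tau_m_i)
    alpha_m = np.exp(-dt / tau_m)

    # out-adjacency: CSR over presynaptic neurons (= CSC of the post x pre matrix)
    out = network.weights.T.tocsr()
    out.sort_indices()

    n_steps = int(round(duration * 1000.0 / dt))
    sp_n, sp_t, bad_neuron, bad_step = _run_lif(
        n_steps,
        dt,
        v0.copy(),
        mu,
        alpha_m,
        cfg.v_threshold,
        cfg.v_reset,
        ref_steps,
        np.exp(-dt / cfg.tau_decay_e),
        np.exp(-dt / cfg.tau_decay_i),
        np.exp(-dt / cfg.tau_rise),
        1.0 / (cfg.tau_decay_e - cfg.tau_rise),
        1.0 / (cfg.tau_decay_i - cfg.tau_rise),
        out.indptr.astype(np.int64),
        out.indices.astype(np.int64),
        out.data.astype(np.float64),
        ne,
    )
    if bad_neuron >= 0:
        raise SimulationError(
            f"non-finite voltage for neuron {bad_neuron} "
            f"at t = {bad_step * dt / 1000.0:.4f} s"
        )
    return SpikeRecord(
        neuron=np.asarray(sp_n), time=np.asarray(sp_t) / 1000.0, duration=duration,
        config=cfg,
    )
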