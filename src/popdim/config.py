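"""Network configuration: parameters of the balanced E/I spiking model.

Voltages are normalized so that 0 corresponds to rest (about -65 mV in a
biological neuron) and 1 to spike threshold (about -50 mV).  Times are in
milliseconds inside the simulator and in seconds at all file interfaces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised when a NetworkConfig violates its invariants."""


@dataclass
class NetworkConfig:
    """All parameters of a clustered or non-clustered balanced network.

    Defaults are the canonical non-clustered values: 4000 excitatory and
    1000 inhibitory leaky integrate-and-fire neurons, membrane time
    constants 15 ms (E) / 10 ms (I), per-neuron bias drawn uniformly from
    [1.1, 1.2] (E) or [1.0, 1.05] (I), threshold 1, reset 0, 5 ms absolute
    refractoriness.  Synapses are difference-of-exponentials filters with
    rise time 1 ms and decay 3 ms (excitatory) / 2 ms (inhibitory).

    ``n_clusters > 0`` switches on clustered excitatory connectivity:
    within-cluster E->E pairs connect with probability ``p_in_EE`` and
    weight ``J_in_EE``, between-cluster pairs with ``p_out_EE`` /
    ``J_out_EE``.  The pair-count-weighted mean of the two probabilities
    must recover the homogeneous ``p_EE``.
    """

    n_excitatory: int = 4000
    n_inhibitory: int = 1000
    # membrane time constants, ms
    tau_m_e: float = 15.0
    tau_m_i: float = 10.0
    # per-neuron constant bias, uniform bounds (normalized voltage)
    bias_range_e: tuple[float, float] = (1.1, 1.2)
    bias_range_i: tuple[float, float] = (1.0, 1.05)
    v_threshold: float = 1.0
    v_reset: float = 0.0
    refractory: float = 5.0  # ms, absolute
    # synaptic filter time constants, ms (rise shared; decay per presyn class)
    tau_rise: float = 1.0
    tau_decay_e: float = 3.0
    tau_decay_i: float = 2.0
    # synaptic weights J[post, pre]
    J_EE: float = 0.024
    J_EI: float = -0.045
    J_IE: float = 0.014
    J_II: float = -0.057
    # connection probabilities p[post, pre]
    p_EE: float = 0.2
    p_EI: float = 0.5
    p_IE: float = 0.5
    p_II: float = 0.5
    # clustered excitatory structure (n_clusters = 0 -> non-clustered)
    n_clusters: int = 0
    cluster_size: int = 80
    p_in_EE: float = 0.4854
    p_out_EE: float = 0.1942
    J_in_EE: float = 0.0456
    J_out_EE: float = 0.024
    # numerics
    dt: float = 0.05  # integration step, ms
    burn_in: float = 2.0  # discarded initial interval, s

    @property
    def clustered(self) -> bool:
        return self.n_clusters > 0

    @property
    def n_neurons(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    def weighted_mean_p_EE(self) -> float:
        """Pair-count-weighted mean of p_in_EE and p_out_EE.

        For clustered configs this must equal the homogeneous ``p_EE``:
        a fraction (c-1)/(N_E-1) of ordered E->E pairs is within-cluster.
        """
        if not self.clustered:
            return self.p_EE
        f_in = (self.cluster_size - 1) / (self.n_excitatory - 1)
        return f_in * self.p_in_EE + (1.0 - f_in) * self.p_out_EE

    def validate(self) -> None:
        probs = [self.p_EE, self.p_EI, self.p_IE, self.p_II]
        if self.clustered:
            probs += [self.p_in_EE, self.p_out_EE]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("connection probabilities must lie in [0, 1]")
        if not self.v_reset < self.v_threshold:
            raise ConfigurationError("v_reset must be below v_threshold")
        for tau2 in (self.tau_decay_e, self.tau_decay_i):
            if not self.tau_rise < tau2:
                raise ConfigurationError("tau_rise must be below every tau_decay")
        if self.n_excitatory <= 0 or self.n_inhibitory <= 0:
            raise ConfigurationError("population sizes must be positive")
        if self.dt <= 0 or self.refractory < 0:
            raise ConfigurationError("dt must be positive, refractory non-negative")
        if self.clustered:
            if self.n_clusters * self.cluster_size != self.n_excitatory:
                raise ConfigurationError(
                    f"n_clusters ({self.n_clusters}) x cluster_size "
                    f"({self.cluster_size}) must equal n_excitatory "
                    f"({self.n_excitatory})"
                )
            if abs(self.weighted_mean_p_EE() - self.p_EE) > 5e-4:
                raise ConfigurationError(
                    "pair-weighted mean of p_in_EE/p_out_EE does not recover p_EE"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bias_range_e"] = list(d["bias_range_e"])
        d["bias_range_i"] = list(d["bias_range_i"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("bias_range_e", "bias_range_i"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _preset(name: str) -> NetworkConfig:
    text = resources.files("popdim.presets").joinpath(name).read_text()
    return NetworkConfig.from_dict(json.loads(text))


def clustered_paper_config() -> NetworkConfig:
    """Canonical clustered network: 50 clusters of 80 excitatory neurons."""
    return _preset("clustered_paper.json")


def nonclustered_paper_config() -> NetworkConfig:
    """Canonical non-clustered network: homogeneous p_EE = 0.2."""
    return _preset("nonclustered_paper.json")
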