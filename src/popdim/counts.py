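"""Trials x neurons spike-count matrices.

A "trial" is one consecutive bin (default 1 s) of a continuous recording or
simulation, after discarding an initial burn-in; bins are half-open
[t, t + bin_width) and a partial trailing bin is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import SpikeRecord


@dataclass
class CountMatrix:
    """Spike counts with per-neuron metadata.

    ``counts`` has shape (trials, neurons).  Binned spike data are
    non-negative integers; Gaussian synthetic data (see
    :mod:`popdim.synth`) may be real-valued.  ``neuron_ids`` names the
    columns; ``bin_starts`` records each trial's start time in seconds
    (synthetic trials are numbered 0, 1, ...).
    """

    counts: np.ndarray
    neuron_ids: np.ndarray
    bin_width: float = 1.0
    bin_starts: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None  # per column, -1 = none/inhibitory
    burn_in: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a trials x neurons matrix")
        self.neuron_ids = np.asarray(self.neuron_ids)
        if len(self.neuron_ids) != self.counts.shape[1]:
            raise ValueError("neuron_ids length must match the number of columns")
        if len(set(self.neuron_ids.tolist())) != len(self.neuron_ids):
            raise ValueError("duplicate neuron ids")
        if self.bin_starts is None:
            self.bin_starts = self.burn_in + self.bin_width * np.arange(
                self.counts.shape[0]
            )

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Mean counts per second, per neuron."""
        return self.counts.mean(axis=0) / self.bin_width

    def select_neurons(self, idx: np.ndarray) -> "CountMatrix":
        """Column subset by positional index, metadata carried along."""
        idx = np.asarray(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            neuron_ids=self.neuron_ids[idx],
            bin_width=self.bin_width,
            bin_starts=self.bin_starts,
            cluster_labels=None
            if self.cluster_labels is None
            else self.cluster_labels[idx],
            burn_in=self.burn_in,
        )

    def active_neurons(self, min_rate: float = 1.0) -> np.ndarray:
        """Positional indices of neurons with mean rate >= ``min_rate``
        (counts/s) and non-zero count variance.

        FA is undefined for zero-variance units, and near-silent units
        carry no usable covariance signal; screening them out mirrors the
        standard unit-selection step for array recordings.
        """
        rates = self.mean_rates()
        var = self.counts.var(axis=0)
        return np.flatnonzero((rates >= min_rate) & (var > 0))

    def select_trials(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            counts=self.counts[idx],
            neuron_ids=self.neuron_ids,
            bin_width=self.bin_width,
            bin_starts=self.bin_starts[idx],
            cluster_labels=self.cluster_labels,
            burn_in=self.burn_in,
        )


def bin_spike_counts(
    spikes: SpikeRecord,
    bin_width: float = 1.0,
    burn_in: float | None = None,
    neurons: np.ndarray | None = None,
    cluster_labels: np.ndarray | None = None,
) -> CountMatrix:
    """Bin a spike record into a trials x neurons count matrix.

    Events before ``burn_in`` (default: the config's burn-in, else 0) are
    discarded; the remaining span is cut into ``floor((duration - burn_in)
    / bin_width)`` half-open bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if burn_in is None:
        burn_in = spikes.config.burn_in if spikes.config is not None else 0.0
    if burn_in >= spikes.duration:
        raise ValueError("burn_in must be smaller than the record duration")
    if neurons is None:
        if spikes.config is not None:
            neurons = np.arange(spikes.config.n_neurons)
        else:
            neurons = np.unique(spikes.neuron)
    neurons = np.asarray(neurons)
    if len(neurons) == 0:
        raise ValueError("neuron subset must not be empty")

    n_bins = int(np.floor((spikes.duration - burn_in) / bin_width))
    col = np.full(int(neurons.max()) + 1, -1, dtype=np.int64)
    col[neurons] = np.arange(len(neurons))

    keep = (spikes.time >= burn_in) & (spikes.time < burn_in + n_bins * bin_width)
    ev_n = spikes.neuron[keep]
    ev_t = spikes.time[keep]
    in_subset = (ev_n <= neurons.max()) & (col[np.minimum(ev_n, neurons.max())] >= 0)
    ev_n = ev_n[in_subset]
    ev_t = ev_t[in_subset]

    rows = np.floor((ev_t - burn_in) / bin_width).astype(np.int64)
    cols = col[ev_n]
    counts = np.zeros((n_bins, len(neurons)), dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)

    if cluster_labels is None and spikes.config is not None:
        cfg = spikes.config
        if cfg.clustered:
            full = np.full(cfg.n_neurons, -1, dtype=np.int64)
            full[: cfg.n_excitatory] = np.repeat(
                np.arange(cfg.n_clusters), cfg.cluster_size
            )
            cluster_labels = full[neurons]

    return CountMatrix(
        counts=counts,
        neuron_ids=neurons,
        bin_width=bin_width,
        bin_starts=burn_in + bin_width * np.arange(n_bins),
        cluster_labels=cluster_labels,
        burn_in=burn_in,
    )
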