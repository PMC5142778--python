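"""File formats: spike-event tables, count matrices, models, run manifests.

All files are plain text.  Spike records are two-column TSV
(``neuron_id<TAB>time_s``, header line, time-sorted; ``.gz`` accepted).
Count matrices are TSV with a header row of neuron ids and an optional
JSON sidecar (``<name>.meta.json``) holding bin width, burn-in and cluster
labels.  Neuron ids are 0-based integers; times are seconds; bins are
half-open.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .fa import FAModel
from .simulate import SpikeRecord


class ParseError(ValueError):
    pass


def _opener(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def write_spikes(spikes: SpikeRecord, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")
    with opener as fh:
        fh.write("neuron_id\ttime_s\n")
        for n, t in zip(spikes.neuron, spikes.time):
            fh.write(f"{int(n)}\t{t:.6f}\n")


def read_spikes(
    path: str | Path, duration: float | None = None, lenient: bool = False
) -> SpikeRecord:
    """Read a two-column spike TSV.  Out-of-order rows are an error unless
    ``lenient`` (then sorted with a warning)."""
    import warnings

    path = Path(path)
    neurons, times = [], []
    with _opener(path) as fh:
        header = fh.readline()
        if not header.startswith("neuron_id"):
            raise ParseError(f"{path}:1: missing header line")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated fields")
            try:
                n = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if n < 0:
                raise ParseError(f"{path}:{lineno}: negative neuron id")
            if t < 0:
                raise ParseError(f"{path}:{lineno}: negative spike time")
            neurons.append(n)
            times.append(t)
    neuron = np.asarray(neurons, dtype=np.int64)
    time = np.asarray(times, dtype=float)
    if np.any(np.diff(time) < 0):
        if not lenient:
            raise ParseError(f"{path}: spike times not sorted (use lenient=True)")
        warnings.warn(f"{path}: sorting out-of-order spike times", stacklevel=2)
        order = np.argsort(time, kind="stable")
        neuron, time = neuron[order], time[order]
    if duration is None:
        duration = float(np.ceil(time[-1])) if len(time) else 0.0
    return SpikeRecord(neuron=neuron, time=time, duration=duration)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(counts.counts, columns=[str(i) for i in counts.neuron_ids])
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "bin_width": counts.bin_width,
        "burn_in": counts.burn_in,
        "bin_starts": np.asarray(counts.bin_starts).tolist(),
        "cluster_labels": None
        if counts.cluster_labels is None
        else np.asarray(counts.cluster_labels).tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta) + "\n")


def read_counts(path: str | Path, require_integer: bool = True) -> CountMatrix:
    """Read a counts TSV (+ optional sidecar metadata).

    Binned spike counts must be non-negative integers; ragged rows,
    non-numeric cells and duplicate neuron ids are parse errors with line
    numbers.
    """
    path = Path(path)
    with _opener(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            neuron_ids = np.array([int(h) for h in header])
        except ValueError:
            raise ParseError(f"{path}:1: header must be integer neuron ids") from None
        if len(set(neuron_ids.tolist())) != len(neuron_ids):
            raise ParseError(f"{path}:1: duplicate neuron ids")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(neuron_ids):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(neuron_ids)} cells, "
                    f"got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if require_integer:
                for v in vals:
                    if v < 0:
                        raise ParseError(f"{path}:{lineno}: negative count")
                    if v != int(v):
                        raise ParseError(f"{path}:{lineno}: non-integer count")
            rows.append(vals)
    arr = np.asarray(rows)
    if require_integer:
        arr = arr.astype(np.int64)

    meta_path = _sidecar(path)
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = {
            "bin_width": meta.get("bin_width", 1.0),
            "burn_in": meta.get("burn_in", 0.0),
        }
        if meta.get("bin_starts") is not None:
            kwargs["bin_starts"] = np.asarray(meta["bin_starts"])
        if meta.get("cluster_labels") is not None:
            kwargs["cluster_labels"] = np.asarray(meta["cluster_labels"])
    return CountMatrix(counts=arr, neuron_ids=neuron_ids, **kwargs)


def write_model(model: FAModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()) + "\n")


def read_model(path: str | Path) -> FAModel:
    return FAModel.from_dict(json.loads(Path(path).read_text()))


def write_manifest(
    out_path: str | Path,
    command: str,
    seeds: dict,
    inputs: list[str],
    outputs: list[str],
    config: dict | None = None,
) -> Path:
    """One manifest JSON per CLI invocation, written next to the outputs."""
    from . import __version__

    payload = {
        "command": command,
        "seeds": seeds,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "config_hash": None
        if config is None
        else hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
        "version": __version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    out = Path(out_path)
    manifest = out.with_suffix(out.suffix + ".manifest.json")
    manifest.write_text(json.dumps(payload, indent=2) + "\n")
    return manifest
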