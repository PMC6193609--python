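"""Spike-data readers/writers and run manifests.

Spike output is one two-column whitespace-delimited text file per population
(neuron index local to the population, spike time in ms) plus a JSON manifest
recording the population order, sizes, recorded counts, step, duration and
seeds.  Re-reading a run directory reproduces the :class:`SpikeData`
bit-exactly for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .simulator import SpikeData

MANIFEST_NAME = "manifest.json"


def _spike_file(run_dir: Path, label: str) -> Path:
    return run_dir / f"spikes-{label}.txt"


def write_spikes(run_dir, spikes: SpikeData) -> Path:
    """Write per-population spike text files and the run manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for label, (idx, t) in spikes.trains.items():
        data = np.column_stack([idx.astype(float), t])
        np.savetxt(_spike_file(run_dir, label), data, fmt="%d %.1f")
    manifest = {
        "format": "mam-run",
        "populations": spikes.populations,
        "sizes": spikes.sizes,
        "recorded": spikes.recorded,
        "duration_ms": spikes.duration,
        "h_ms": spikes.h,
        "seed": spikes.seed,
        "record_fraction": spikes.record_fraction,
    }
    with open(run_dir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return run_dir


def read_spikes(run_dir) -> SpikeData:
    """Read a run directory written by :func:`write_spikes`."""
    run_dir = Path(run_dir)
    with open(run_dir / MANIFEST_NAME) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "mam-run":
        raise ValueError("not a spike-run directory (missing format tag)")
    trains = {}
    for label in manifest["populations"]:
        path = _spike_file(run_dir, label)
        if path.exists() and path.stat().st_size > 0:
            raw = np.loadtxt(path, ndmin=2)
            trains[label] = (raw[:, 0].astype(np.int64), raw[:, 1])
        else:
            trains[label] = (np.empty(0, dtype=np.int64), np.empty(0))
    return SpikeData(
        trains=trains,
        sizes={k: int(v) for k, v in manifest["sizes"].items()},
        recorded={k: int(v) for k, v in manifest["recorded"].items()},
        duration=float(manifest["duration_ms"]),
        h=float(manifest["h_ms"]),
        seed=int(manifest["seed"]),
        record_fraction=float(manifest["record_fraction"]),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
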