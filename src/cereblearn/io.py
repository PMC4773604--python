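"""On-disk formats: spike rasters, weight snapshots, trial logs, STDP dumps.

Everything is columnar text. Rasters are two-column TSV sorted by time with
a header comment carrying a topology hash and the seed; weight snapshots
are one CSV per projection plus a small manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lif import SpikeEvent
from .network import NetworkTopology, snapshot_weights

__all__ = [
    "topology_hash",
    "write_raster",
    "read_raster",
    "write_weight_snapshot",
    "read_weight_snapshot",
    "write_trial_log",
    "write_decoded_output",
    "write_stdp_curves",
]


def topology_hash(topology: NetworkTopology) -> str:
    h = hashlib.sha256()
    for name, proj in sorted(topology.projections.items()):
        h.update(name.encode())
        h.update(proj.pre_ids.tobytes())
        h.update(proj.post_ids.tobytes())
        h.update(np.asarray(proj.weights, float).tobytes())
    return h.hexdigest()[:16]


def write_raster(path, events, network_hash: str = "", seed: int | None = None):
    events = sorted(events, key=lambda e: (e.time, e.neuron_id))
    with open(path, "w") as f:
        f.write(f"# network={network_hash} seed={seed}\n")
        f.write("time_s\tneuron_id\n")
        for ev in events:
            f.write(f"{ev.time:.6f}\t{ev.neuron_id}\n")


def read_raster(path):
    with open(path) as f:
        header = f.readline().strip()
        df = pd.read_csv(f, sep="\t")
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split() if "=" in tok)
    events = [SpikeEvent(float(t), int(n)) for t, n in zip(df.time_s, df.neuron_id)]
    return events, meta


def write_weight_snapshot(
    directory, topology: NetworkTopology, trial: int | None = None
) -> Path:
    """Per-projection CSV `pre_id,post_id,weight_nS` plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = snapshot_weights(topology)
    files = {}
    for name, tab in tables.items():
        fname = name.replace("->", "_to_") + ".csv"
        pd.DataFrame(tab).to_csv(directory / fname, index=False)
        files[name] = fname
    manifest = {
        "case": topology.config.case,
        "trial": trial,
        "seed": topology.seed,
        "config_hash": topology_hash(topology),
        "files": files,
    }
    with open(directory / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return directory


def read_weight_snapshot(directory) -> tuple[dict, dict]:
    directory = Path(directory)
    with open(directory / "manifest.json") as f:
        manifest = json.load(f)
    tables = {
        name: pd.read_csv(directory / fname)
        for name, fname in manifest["files"].items()
    }
    return tables, manifest


def write_trial_log(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_decoded_output(path, y: np.ndarray, dt: float) -> None:
    y = np.atleast_2d(np.asarray(y, float).T).T
    rows = []
    for s in range(y.shape[0]):
        for ch in range(y.shape[1]):
            rows.append((s, s * dt, ch, y[s, ch]))
    pd.DataFrame(rows, columns=["step", "time_s", "channel", "value"]).to_csv(
        path, index=False
    )


def write_stdp_curves(path, pfpc, mfdcn, pcdcn, dt_ms_max: float = 150.0) -> None:
    """Dump the per-rule weight-change curves vs. spike-timing offset."""
    from .plasticity import mfdcn_kernel, pcdcn_hebbian, pcdcn_symmetric, pfpc_ltd_kernel

    dts = np.linspace(-dt_ms_max, dt_ms_max, 301)
    rows = []
    for d in dts:
        t = d / 1000.0
        rows.append(
            (
                d,
                -pfpc.ltd_scale * pfpc_ltd_kernel(max(t, 0.0) / pfpc.tau_ltd),
                -mfdcn.ltd_scale * mfdcn_kernel(t / mfdcn.sigma, mfdcn.beta),
                pcdcn_hebbian(t, pcdcn),
                pcdcn_symmetric(t, pcdcn),
            )
        )
    pd.DataFrame(
        rows,
        columns=["delta_t_ms", "pfpc_ltd", "mfdcn_ltd", "pcdcn_hebbian", "pcdcn_symmetric"],
    ).to_csv(path, index=False)
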