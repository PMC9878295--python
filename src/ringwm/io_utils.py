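"""Result persistence: run manifests, rasters, decoded trajectories, tables."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .protocol import BatchResult, TrialRecord

__all__ = ["RunManifest", "write_manifest", "read_manifest",
           "save_raster", "load_raster", "save_trajectories",
           "save_report_table", "batch_summary"]

try:
    from importlib.metadata import version
    _VERSION = version("ringwm")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    base_seed: int
    trial_seeds: list[int]
    created: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S"))
    code_version: str = _VERSION
    platform: str = field(default_factory=platform.platform)
    outputs: dict = field(default_factory=dict)


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(vars(manifest), indent=2))


def read_manifest(path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)


def save_raster(path, spike_t, spike_neuron, fmt: str = "csv") -> None:
    """Raster as (neuron_id, spike_time_ms) delimited text or npz."""
    if fmt == "csv":
        pd.DataFrame({"neuron_id": np.asarray(spike_neuron, dtype=int),
                      "spike_time_ms": np.asarray(spike_t, dtype=float)
                      }).to_csv(path, index=False)
    else:
        np.savez_compressed(path, spike_t=spike_t, spike_neuron=spike_neuron)


def load_raster(path):
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path) as d:
            return d["spike_t"], d["spike_neuron"]
    df = pd.read_csv(path)
    return df["spike_time_ms"].to_numpy(), df["neuron_id"].to_numpy()


def save_trajectories(path, record: TrialRecord) -> None:
    """Decoded trajectories as (t_ms, stimulus_index, theta_deg, alive)."""
    if record.decoded is None:
        raise ValueError("trial was decoded without trajectories")
    rows = []
    for a in range(record.decoded.shape[0]):
        th = record.decoded[a]
        rows.append(pd.DataFrame({
            "t_ms": record.decode_times, "stimulus_index": a,
            "theta_deg": th, "alive": np.isfinite(th).astype(int)}))
    pd.concat(rows).to_csv(path, index=False)


def save_report_table(path, batch: BatchResult) -> None:
    """Per-trial stimuli/reports/fade flags as a delimited table."""
    n, load = batch.stimuli.shape
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(n), load),
        "seed": np.repeat(batch.seeds, load),
        "stimulus_index": np.tile(np.arange(load), n),
        "stimulus_deg": batch.stimuli.ravel(),
        "report_deg": batch.reports.ravel(),
        "faded": batch.faded.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def batch_summary(batch: BatchResult) -> dict:
    """Headline numbers of a batch, JSON-ready."""
    from .analysis import pool_reports
    stats = pool_reports(batch.stimuli, batch.reports)
    return dict(
        n_trials=int(batch.n_trials),
        load=int(batch.stimuli.shape[1]),
        fade_fraction=float(batch.faded.mean()),
        error_sd_deg=stats.error_sd,
        fit_mu_deg=float(stats.fit_mu),
        fit_sigma_deg=float(stats.fit_sigma),
        fit_sse=float(stats.sse),
        n_modes=int(stats.n_modes),
        mode_locations_deg=[float(x) for x in stats.mode_locations],
    )


def save_batch(out_dir, cfg: NetworkConfig, batch: BatchResult) -> None:
    """Write the standard output bundle for a batch run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_report_table(out / "reports.csv", batch)
    summary = batch_summary(batch)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest = RunManifest(config=cfg.to_dict(),
                           base_seed=int(cfg.protocol.base_seed),
                           trial_seeds=[int(s) for s in batch.seeds],
                           outputs={"reports": "reports.csv",
                                    "summary": "summary.json"})
    write_manifest(manifest, out / "manifest.json")
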