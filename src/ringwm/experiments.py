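"""Named experiment configurations and the experiment runner.

Each experiment is the package's configuration for one of the standard
conditions: the default heterogeneous+STP network, the homogeneous control
(b = 10,000), the plasticity-removed control (u*x -> 1), the
membrane-potential and STP-variable recordings, the drift-diffusion
reference, and the three-peak connectivity variant.  Every experiment comes
in a full (paper-scale) profile and a reduced desk-scale profile (about
20x smaller: fewer trials, 1,000 ms delay).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .io_utils import save_batch
from .protocol import run_batch

__all__ = ["EXPERIMENTS", "experiment_config", "run_experiment"]

# full-scale trial counts follow the reference protocol (4,000 trials,
# 3,000 ms delay); reduced profiles are for desk-scale runs
_FULL = dict(n_trials=4000, t_end=3150.0)
_REDUCED = dict(n_trials=160, t_end=1150.0)


def _base(**overrides) -> NetworkConfig:
    cfg = NetworkConfig()
    con = overrides.pop("connectivity", {})
    stp = overrides.pop("stp", {})
    prot = overrides.pop("protocol", {})
    sim = overrides.pop("sim", {})
    for k, v in con.items():
        setattr(cfg.connectivity, k, v)
    for k, v in stp.items():
        setattr(cfg.stp, k, v)
    for k, v in prot.items():
        setattr(cfg.protocol, k, v)
    for k, v in sim.items():
        setattr(cfg.sim, k, v)
    return cfg.validate()


EXPERIMENTS = {
    "fig2_default": dict(),
    "fig3_homogeneous": dict(connectivity=dict(b=10000.0)),
    "fig4_no_stp": dict(stp=dict(enabled=False)),
    "fig5_potentials": dict(sim=dict(record_V=True)),
    "fig6_stp_maps": dict(sim=dict(record_stp=True)),
    "fig8_three_peaks": dict(connectivity=dict(n_peaks=3)),
    "fig7_sde": dict(),   # handled by the sde module, see run_experiment
}


def experiment_config(name: str, reduced: bool = True) -> NetworkConfig:
    """The configuration of a named experiment (reduced or full profile)."""
    if name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    scale = _REDUCED if reduced else _FULL
    over = dict(EXPERIMENTS[name])
    prot = dict(over.get("protocol", {}))
    prot.update(scale)
    over["protocol"] = prot
    return _base(**over)


def run_experiment(name: str, out_dir, reduced: bool = True,
                   seed: int | None = None, n_trials: int | None = None,
                   progress: bool = True):
    """Execute a named experiment and write its output bundle."""
    out = Path(out_dir)
    if name == "fig7_sde":
        from .analysis import pool_reports
        from .sde import SDEParams, run_sde_batch
        params = SDEParams()
        res = run_sde_batch(params, n_paths=10_000,
                            seed=seed if seed is not None else 0)
        stats = pool_reports(res["stimuli"], res["reports"])
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "sde_reports.csv",
                   np.column_stack([res["stimuli"], res["reports"],
                                    res["errors"]]),
                   delimiter=",", header="stimulus_deg,report_deg,error_deg",
                   comments="")
        (out / "summary.json").write_text(json.dumps(dict(
            n_paths=10_000, error_sd_deg=stats.error_sd,
            n_modes=int(stats.n_modes),
            mode_locations_deg=[float(x) for x in stats.mode_locations]),
            indent=2))
        return stats
    cfg = experiment_config(name, reduced=reduced)
    if seed is not None:
        cfg.protocol.base_seed = int(seed)
    if n_trials is not None:
        cfg.protocol.n_trials = int(n_trials)
    batch = run_batch(cfg, progress=progress, out_dir=out / "chunks")
    save_batch(out, cfg, batch)
    return batch
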