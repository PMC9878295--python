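"""Trial protocol: cue arrays, seeded single trials, and batch simulation.

A trial presents ``load`` cue currents (Gaussian bumps of width sigma_s on
the ring, active during [t_cue_on, t_cue_off)) to the E population, then
lets the network evolve until t_end.  Stimulus angles are sampled uniformly
from the color wheel, re-drawn until all pairwise circular separations
exceed min_sep.  Every random ingredient of trial k draws from its own
counter-seeded stream derived from base_seed + k (background noise, guess
reports, stimulus positions), so any trial reproduces bit-for-bit on its
own or inside any batch.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError, NetworkConfig
from .connectivity import HeterogeneousProfile, build_profile
from .decoding import decode_trial, estimate_rates
from .dynamics import SimulationResult, simulate_batch

__all__ = [
    "TrialRecord",
    "BatchResult",
    "sample_stimuli",
    "cue_current",
    "build_cue_profiles",
    "run_trial",
    "run_batch",
    "calibrate_defaults",
    "stimulus_rng",
    "guess_rng",
]

# stream ids for the per-trial counter-based generators
_STREAM_NOISE = 0     # consumed inside simulate_batch
_STREAM_GUESS = 1
_STREAM_STIMULI = 2


def stimulus_rng(trial_seed: int) -> np.random.Generator:
    return np.random.default_rng([int(trial_seed), _STREAM_STIMULI])


def guess_rng(trial_seed: int) -> np.random.Generator:
    return np.random.default_rng([int(trial_seed), _STREAM_GUESS])


def sample_stimuli(n: int, min_sep_deg: float,
                   rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform cue angles (degrees), rejection-sampled for spacing.

    The whole array is re-drawn until every pairwise circular separation
    exceeds ``min_sep_deg``, which preserves uniform marginals.
    """
    if n < 1:
        raise ConfigError("sample_stimuli: n must be >= 1")
    if n * min_sep_deg >= 360.0:
        raise ConfigError(
            f"sample_stimuli: {n} stimuli with min separation "
            f"{min_sep_deg} deg cannot fit on the circle")
    while True:
        ang = rng.uniform(0.0, 360.0, n)
        if n == 1:
            return ang
        d = np.abs(ang[:, None] - ang[None, :])
        d = np.minimum(d, 360.0 - d)
        iu = np.triu_indices(n, 1)
        if (d[iu] > min_sep_deg).all():
            return ang


def cue_current(theta: np.ndarray, stimuli_deg, I0: float,
                sigma_s: float, t: float, t_cue_on: float,
                t_cue_off: float) -> np.ndarray:
    """Cue current (nA) onto each E neuron at time t.

    Zero outside [t_cue_on, t_cue_off); inside, a sum of normalized
    Gaussian profiles I0/(sqrt(2 pi) sigma_s) * exp(-d^2 / 2 sigma_s^2)
    over the circular distance d to each stimulus.  ``sigma_s`` in radians.
    """
    if not (t_cue_on <= t < t_cue_off):
        return np.zeros_like(theta)
    return _cue_profile(theta, stimuli_deg, I0, sigma_s)


def _cue_profile(theta, stimuli_deg, I0, sigma_s):
    stim = np.deg2rad(np.atleast_1d(np.asarray(stimuli_deg, dtype=float)))
    d = np.abs(theta[:, None] - stim[None, :])
    d = np.minimum(d, 2 * np.pi - d)
    amp = I0 / (np.sqrt(2 * np.pi) * sigma_s)
    return (amp * np.exp(-d ** 2 / (2 * sigma_s ** 2))).sum(axis=1)


def build_cue_profiles(profile: HeterogeneousProfile, stimuli_deg_batch,
                       I0: float, sigma_s: float) -> np.ndarray:
    """(N_E, B) cue currents for a batch of per-trial stimulus arrays."""
    cols = [_cue_profile(profile.theta, s, I0, sigma_s)
            for s in stimuli_deg_batch]
    return np.stack(cols, axis=1)


@dataclass
class TrialRecord:
    """Everything recorded about one trial."""

    seed: int
    stimuli: np.ndarray              # cue angles, degrees, (load,)
    reports: np.ndarray              # per-stimulus report, degrees
    faded: np.ndarray                # per-stimulus fade flag
    decoded: np.ndarray | None = None  # (load, n_times) degrees, NaN=undefined
    decode_times: np.ndarray | None = None
    raster_t: np.ndarray | None = None
    raster_neuron: np.ndarray | None = None
    V_samples: np.ndarray | None = None
    u_samples: np.ndarray | None = None
    x_samples: np.ndarray | None = None
    sample_times: np.ndarray | None = None


@dataclass
class BatchResult:
    """Stacked per-trial outcomes of a batch run."""

    config: NetworkConfig
    seeds: np.ndarray
    stimuli: np.ndarray             # (n_trials, load) degrees
    reports: np.ndarray             # (n_trials, load) degrees
    faded: np.ndarray               # (n_trials, load) bool
    records: list[TrialRecord] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.stimuli.shape[0]


def _decode_batch(cfg: NetworkConfig, profile: HeterogeneousProfile,
                  res: SimulationResult, seeds, stimuli,
                  keep_rasters: bool, keep_trajectories: bool):
    """Decode every trial of a simulated batch into TrialRecords."""
    dec = cfg.decode
    records = []
    for k, seed in enumerate(seeds):
        t, n = res.trial_raster(k)
        rate_map = estimate_rates(t, n, cfg.connectivity.N_E,
                                  cfg.protocol.t_end, dec.rate_window,
                                  dec.smooth_sigma)
        decoded, alive, faded, reports = decode_trial(
            rate_map, profile.theta, stimuli[k], dec, guess_rng(seed),
            window_only=not keep_trajectories)
        rec = TrialRecord(
            seed=int(seed), stimuli=np.atleast_1d(stimuli[k]),
            reports=reports, faded=faded)
        if keep_trajectories:
            rec.decoded = decoded
            rec.decode_times = rate_map.times
        if keep_rasters:
            rec.raster_t, rec.raster_neuron = t, n
        if res.V_samples is not None:
            rec.V_samples = res.V_samples[:, :, k]
        if res.u_samples is not None:
            rec.u_samples = res.u_samples[:, :, k]
            rec.x_samples = res.x_samples[:, :, k]
        if res.sample_times is not None:
            rec.sample_times = res.sample_times
        records.append(rec)
    return records


def run_trial(cfg: NetworkConfig, seed: int,
              stimuli_deg=None, profile: HeterogeneousProfile | None = None,
              keep_raster: bool = True) -> TrialRecord:
    """Simulate and decode a single trial (deterministic in (cfg, seed))."""
    cfg.validate()
    if profile is None:
        profile = build_profile(cfg.connectivity)
    prot = cfg.protocol
    if stimuli_deg is None:
        stimuli_deg = sample_stimuli(prot.load, prot.min_sep_deg,
                                     stimulus_rng(seed))
    stimuli_deg = np.atleast_1d(np.asarray(stimuli_deg, dtype=float))
    cues = build_cue_profiles(profile, [stimuli_deg], prot.I0, prot.sigma_s)
    res = simulate_batch(cfg, profile, [seed], cue_profiles=cues)
    return _decode_batch(cfg, profile, res, [seed], [stimuli_deg],
                         keep_raster, True)[0]


def run_batch(cfg: NetworkConfig, profile: HeterogeneousProfile | None = None,
              stimuli_list=None, n_trials: int | None = None,
              keep_rasters: bool | None = None,
              keep_trajectories: bool = False,
              chunk_size: int = 128, out_dir=None,
              progress: bool = False) -> BatchResult:
    """Run a batch of trials with seeds base_seed + k.

    ``stimuli_list`` overrides stimulus sampling (one angle array per
    trial, honored verbatim).  Trials are simulated in vectorized chunks of
    ``chunk_size``.  With ``out_dir`` set, each completed chunk is
    persisted as an .npz plus a manifest, and an interrupted batch resumes
    from the completed chunks.
    """
    cfg.validate()
    if profile is None:
        profile = build_profile(cfg.connectivity)
    prot = cfg.protocol
    n = n_trials if n_trials is not None else prot.n_trials
    seeds = prot.base_seed + np.arange(n)
    if stimuli_list is None:
        stimuli = np.stack([
            sample_stimuli(prot.load, prot.min_sep_deg, stimulus_rng(s))
            for s in seeds])
    else:
        stimuli = np.stack(
            [np.atleast_1d(np.asarray(s, dtype=float)) for s in stimuli_list])
        if stimuli.shape[0] != n:
            raise ConfigError("run_batch: stimuli_list length != n_trials")
    if keep_rasters is None:
        keep_rasters = n <= 200
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    all_records: list[TrialRecord] = []
    reports = np.zeros_like(stimuli)
    faded = np.zeros(stimuli.shape, dtype=bool)
    t0 = time.time()
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        chunk_file = (out_path / f"chunk_{start:06d}.npz"
                      if out_path is not None else None)
        if chunk_file is not None and chunk_file.exists():
            with np.load(chunk_file) as d:
                reports[start:stop] = d["reports"]
                faded[start:stop] = d["faded"]
            continue
        cues = build_cue_profiles(profile, stimuli[start:stop],
                                  prot.I0, prot.sigma_s)
        res = simulate_batch(cfg, profile, seeds[start:stop],
                             cue_profiles=cues)
        recs = _decode_batch(cfg, profile, res, seeds[start:stop],
                             stimuli[start:stop], keep_rasters,
                             keep_trajectories)
        for k, rec in enumerate(recs):
            reports[start + k] = rec.reports
            faded[start + k] = rec.faded
        all_records.extend(recs)
        if chunk_file is not None:
            np.savez_compressed(chunk_file, seeds=seeds[start:stop],
                                stimuli=stimuli[start:stop],
                                reports=reports[start:stop],
                                faded=faded[start:stop])
        if progress:
            done = stop
            el = time.time() - t0
            print(f"  [{done}/{n} trials, {el:.0f} s elapsed]", flush=True)
    if out_path is not None:
        manifest = dict(n_trials=int(n), base_seed=int(prot.base_seed),
                        load=int(prot.load), t_end=float(prot.t_end),
                        completed=int(n))
        (out_path / "batch_manifest.json").write_text(
            json.dumps(manifest, indent=2))
    return BatchResult(config=cfg, seeds=seeds, stimuli=stimuli,
                       reports=reports, faded=faded, records=all_records)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    """No parameter combination satisfied the calibration criteria."""


def calibrate_defaults(cfg: NetworkConfig, G_EE_grid, G_IE_grid,
                       n_check_trials: int = 4, t_end: float | None = None,
                       spont_max: float = 5.0, peak_range=(20.0, 100.0),
                       persist_frac: float = 0.75, verbose: bool = False):
    """Grid-search conductance scales against the two stability criteria.

    For each (G_EE, G_IE) candidate: (a) a no-cue run must keep the mean E
    rate below ``spont_max`` Hz; (b) load-1 cued trials must keep a bump
    alive to t_end (peak smoothed subpopulation rate above baseline) with
    final peak rate inside ``peak_range`` in at least ``persist_frac`` of
    trials.  Returns (calibrated config, report rows); raises
    :class:`CalibrationError` with the nearest miss if nothing passes.
    """
    cfg = NetworkConfig.from_dict(cfg.to_dict())  # deep copy
    if t_end is not None:
        cfg.protocol.t_end = t_end
    rows = []
    best = None
    for gee in G_EE_grid:
        for gie in G_IE_grid:
            cfg.connectivity.G_EE_NMDA = float(gee)
            cfg.connectivity.G_IE_GABA = float(gie)
            profile = build_profile(cfg.connectivity)
            prot = cfg.protocol
            # (a) spontaneous stability, one no-cue trial
            res = simulate_batch(cfg, profile, [prot.base_seed])
            spont = res.spike_t.size / (cfg.connectivity.N_E
                                        * prot.t_end / 1000.0)
            # (b) persistence of a cued bump
            seeds = prot.base_seed + 1 + np.arange(n_check_trials)
            stim = [sample_stimuli(1, 0.0, stimulus_rng(s)) for s in seeds]
            cues = build_cue_profiles(profile, stim, prot.I0, prot.sigma_s)
            resc = simulate_batch(cfg, profile, seeds, cue_profiles=cues)
            peaks = []
            NE = cfg.connectivity.N_E
            for k in range(n_check_trials):
                t, nn = resc.trial_raster(k)
                sel = t > prot.t_end - 100.0
                counts = np.bincount(nn[sel], minlength=NE) / 0.1  # Hz
                from scipy.ndimage import gaussian_filter1d
                sm = gaussian_filter1d(counts.astype(float),
                                       cfg.decode.smooth_sigma, mode="wrap")
                peaks.append(float(sm.max()))
            peaks = np.array(peaks)
            ok_persist = np.mean((peaks > cfg.decode.baseline)
                                 & (peaks >= peak_range[0])
                                 & (peaks <= peak_range[1]))
            row = dict(G_EE=float(gee), G_IE=float(gie), spont_rate=spont,
                       median_peak=float(np.median(peaks)),
                       persist_frac=float(ok_persist))
            rows.append(row)
            score = (spont < spont_max) * ok_persist
            if verbose:
                print(row, flush=True)
            if spont < spont_max and ok_persist >= persist_frac:
                cal = NetworkConfig.from_dict(cfg.to_dict())
                return cal, rows
            if best is None or score > best[0]:
                best = (score, row)
    raise CalibrationError(
        f"no (G_EE, G_IE) in the grid met the criteria; nearest miss: "
        f"{best[1] if best else 'none'}")
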