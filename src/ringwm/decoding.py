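"""Population-vector decoding of bump-attractor activity.

The pipeline turns a spike raster into a per-neuron firing-rate map on a
1 ms grid (causal boxcar count, optional circular spatial smoothing),
segments supra-baseline activity into contiguous arcs ("bumps"), assigns
each arc to the nearest stimulus, and decodes the remembered color of
stimulus alpha as the argument of the rate-weighted complex sum

    theta_d,alpha(t) = arg sum_{j in N_alpha} r_j(t) exp(i theta_j)

over its subpopulation N_alpha.  A stimulus whose subpopulation stays below
the baseline rate through the end of the trial has "faded": the network has
forgotten it and the report is a uniform random guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import DecodeParams

__all__ = [
    "RateMap",
    "BumpSegmentation",
    "estimate_rates",
    "segment_bumps",
    "decode_angle",
    "detect_fade",
    "make_report",
    "decode_trial",
]


@dataclass
class RateMap:
    """Firing rates (Hz) of each E neuron on a regular time grid."""

    r: np.ndarray          # (N_E, n_times) rates, Hz
    times: np.ndarray      # (n_times,) grid, ms
    window: float          # boxcar length, ms
    kernel_width: float    # circular spatial smoothing sigma, neuron indices

    @property
    def N_E(self) -> int:
        return self.r.shape[0]


@dataclass
class BumpSegmentation:
    """Per-stimulus subpopulations (index arrays) and aliveness flags."""

    subpopulations: list[np.ndarray]
    alive: np.ndarray      # (n_stimuli,) bool


def estimate_rates(spike_t, spike_neuron, N_E: int, t_end: float,
                   window: float = 50.0, smooth_sigma: float = 5.0,
                   grid_step: float = 1.0) -> RateMap:
    """Causal boxcar rate estimate on a regular grid.

    The rate of neuron j at time t is its spike count in (t - window, t]
    divided by the window, optionally smoothed across neighboring neurons
    with a circular Gaussian (``smooth_sigma`` in neuron indices, 0
    disables).  An empty raster yields an all-zero map.
    """
    if window <= 0:
        raise ValueError("estimate_rates: window must be > 0")
    times = np.arange(grid_step, t_end + grid_step / 2, grid_step)
    nT = times.size
    counts = np.zeros((N_E, nT + 1), dtype=np.float32)
    if len(spike_t):
        spike_t = np.asarray(spike_t, dtype=float)
        spike_neuron = np.asarray(spike_neuron, dtype=np.intp)
        # bin index: spike at t falls into grid cell ceil(t/grid_step)
        bins = np.ceil(spike_t / grid_step - 1e-9).astype(np.intp)
        bins = np.clip(bins, 1, nT)
        np.add.at(counts, (spike_neuron, bins), 1.0)
    csum = np.cumsum(counts, axis=1)
    w_bins = max(1, int(round(window / grid_step)))
    lo = np.maximum(0, np.arange(1, nT + 1) - w_bins)
    r = (csum[:, 1:] - csum[:, lo]) * (1000.0 / window)
    if smooth_sigma and smooth_sigma > 0:
        r = gaussian_filter1d(r, smooth_sigma, axis=0, mode="wrap")
    return RateMap(r=r, times=times, window=window,
                   kernel_width=smooth_sigma or 0.0)


def _true_runs(m: np.ndarray):
    """(starts, lengths) of circular runs of True in boolean array m."""
    n = m.size
    starts = np.flatnonzero(m & ~np.roll(m, 1))
    ends = np.flatnonzero(m & ~np.roll(m, -1))
    if starts.size == 0:
        return starts, starts
    # match each start with the first end at or after it (circularly)
    lengths = np.empty_like(starts)
    for k, s in enumerate(starts):
        e = ends[np.searchsorted(ends, s) % ends.size]
        lengths[k] = (e - s) % n + 1
    return starts, lengths


def _circular_runs(mask: np.ndarray, gap_tol: int = 0) -> list[np.ndarray]:
    """Contiguous circular runs of True, bridging gaps of <= gap_tol False."""
    n = mask.size
    m = np.asarray(mask, dtype=bool)
    if m.all():
        return [np.arange(n)]
    if not m.any():
        return []
    if gap_tol > 0:
        gstarts, glengths = _true_runs(~m)
        m = m.copy()
        for s, ln in zip(gstarts, glengths):
            if ln <= gap_tol:
                m[np.arange(s, s + ln) % n] = True
        if m.all():
            return [np.arange(n)]
    starts, lengths = _true_runs(m)
    return [np.arange(s, s + ln) % n for s, ln in zip(starts, lengths)]


def segment_bumps(rates: np.ndarray, theta: np.ndarray, stimuli_deg,
                  baseline: float = 2.0, gap_tol: int = 3,
                  min_width: int = 3, merge_tol_deg: float = 30.0,
                  claim_tol_deg: float = 60.0) -> BumpSegmentation:
    """Assign supra-baseline arcs of activity to stimuli.

    ``rates``: (N_E,) instantaneous rate profile.  Neurons above
    ``baseline`` form contiguous circular arcs (gaps of <= ``gap_tol``
    neurons are bridged; arcs of fewer than ``min_width`` neurons are
    background-noise blips and are dropped).  Each arc belongs to the
    stimulus nearest (by circular distance) to its rate-weighted center of
    mass; when several arcs map to one stimulus the strongest (largest
    rate mass) is kept.  A stimulus left without an arc adopts the arc of
    another stimulus if that arc's center lies within ``merge_tol_deg``
    (two bumps that have coalesced report together); otherwise it is not
    alive (its bump has faded or never formed).
    """
    stimuli = np.deg2rad(np.asarray(stimuli_deg, dtype=float))
    n_stim = stimuli.size
    arcs = [a for a in _circular_runs(np.asarray(rates) > baseline, gap_tol)
            if a.size >= min_width]
    subpops: list[np.ndarray] = [np.empty(0, dtype=np.intp)] * n_stim
    centers = np.full(n_stim, np.nan)
    best_mass = np.zeros(n_stim)
    for arc in arcs:
        mass = float(rates[arc].sum())
        if mass <= 0:
            continue
        center = np.angle(np.sum(rates[arc] * np.exp(1j * theta[arc])))
        d = np.abs(np.angle(np.exp(1j * (stimuli - center))))
        alpha = int(np.argmin(d))
        if d[alpha] > np.deg2rad(claim_tol_deg):
            continue
        if mass > best_mass[alpha]:
            subpops[alpha] = np.asarray(arc, dtype=np.intp)
            best_mass[alpha] = mass
            centers[alpha] = center
    # merged bumps: an empty stimulus adopts a nearby claimed arc
    tol = np.deg2rad(merge_tol_deg)
    for a in range(n_stim):
        if subpops[a].size:
            continue
        d = np.abs(np.angle(np.exp(1j * (centers - stimuli[a]))))
        d[np.isnan(centers)] = np.inf
        if np.isfinite(d).any() and d.min() <= tol:
            subpops[a] = subpops[int(np.argmin(d))]
    alive = np.array([sp.size > 0 for sp in subpops])
    return BumpSegmentation(subpopulations=subpops, alive=alive)


def decode_angle(rates: np.ndarray, theta: np.ndarray,
                 subpop: np.ndarray) -> float:
    """Population-vector angle (degrees in [0, 360)) of a subpopulation.

    Returns NaN when the subpopulation is empty or carries zero rate
    (undefined decode; the caller falls back to fade handling).
    """
    subpop = np.asarray(subpop, dtype=np.intp)
    if subpop.size == 0:
        return float("nan")
    r = np.asarray(rates, dtype=float)[subpop]
    if not r.sum() > 0:
        return float("nan")
    z = np.sum(r * np.exp(1j * theta[subpop]))
    if z == 0:
        return float("nan")
    return float(np.rad2deg(np.angle(z)) % 360.0)


def detect_fade(rate_map: RateMap, subpop: np.ndarray, t_end: float,
                window: float = 100.0, baseline: float = 2.0) -> bool:
    """True iff the subpopulation stays below baseline through the final window.

    A bump that is silent (or absent) during the last ``window`` ms of the
    trial no longer carries the stimulus; the memory is lost.
    """
    subpop = np.asarray(subpop, dtype=np.intp)
    if subpop.size == 0:
        return True
    sel = rate_map.times > t_end - window
    seg = rate_map.r[np.ix_(subpop, np.flatnonzero(sel))]
    return bool((seg.max(axis=0) < baseline).all())


def make_report(decoded_end: float, faded: bool,
                guess_rng: np.random.Generator) -> float:
    """Final report: the decoded angle, or a uniform guess if faded."""
    if faded or not np.isfinite(decoded_end):
        return float(guess_rng.uniform(0.0, 360.0))
    return float(decoded_end % 360.0)


def decode_trial(rate_map: RateMap, theta: np.ndarray, stimuli_deg,
                 params: DecodeParams, guess_rng: np.random.Generator,
                 window_only: bool = False):
    """Full decoding of one trial: trajectories, fade flags, reports.

    Returns (decoded (n_stim, n_times) degrees with NaN where undefined,
    alive (n_stim, n_times) bool, faded (n_stim,) bool,
    reports (n_stim,) degrees).  With ``window_only`` the trajectory is
    decoded only inside the final fade window (all that reports and fade
    flags need); earlier grid points stay NaN.
    """
    stimuli_deg = np.atleast_1d(np.asarray(stimuli_deg, dtype=float))
    n_stim = stimuli_deg.size
    nT = rate_map.times.size
    decoded = np.full((n_stim, nT), np.nan)
    alive = np.zeros((n_stim, nT), dtype=bool)
    t_last = float(rate_map.times[-1])
    if window_only:
        t_idx = np.flatnonzero(rate_map.times > t_last - params.fade_window)
    else:
        t_idx = np.arange(nT)
    for ti in t_idx:
        seg = segment_bumps(rate_map.r[:, ti], theta, stimuli_deg,
                            baseline=params.baseline, gap_tol=params.gap_tol,
                            min_width=params.min_arc_width,
                            merge_tol_deg=params.merge_tol_deg,
                            claim_tol_deg=params.claim_tol_deg)
        for a in range(n_stim):
            alive[a, ti] = seg.alive[a]
            decoded[a, ti] = decode_angle(rate_map.r[:, ti], theta,
                                          seg.subpopulations[a])
    t_end = t_last
    faded = np.zeros(n_stim, dtype=bool)
    reports = np.zeros(n_stim)
    fade_sel = rate_map.times > t_end - params.fade_window
    for a in range(n_stim):
        # faded iff no supra-baseline arc maps to this stimulus at any
        # point of the final window
        faded[a] = not alive[a, fade_sel].any()
        # report from the last defined decode in the fade window
        last = decoded[a, fade_sel]
        defined = np.isfinite(last)
        end_val = last[defined][-1] if defined.any() else float("nan")
        reports[a] = make_report(end_val, faded[a], guess_rng)
    return decoded, alive, faded, reports
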