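"""Synthetic fixtures with known ground truth for decoder/analysis tests.

Rasters are inhomogeneous-Poisson spike trains around parameterized bump
trajectories (stable, drifting, fading, or merged), plus uniform background
noise; report samples come from von Mises mixtures.  Every fixture returns
its ground truth so tests can assert recovery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_fixture"]

_KINDS = ("stable_bump", "drifting_bump", "fading_bump", "merged_bumps",
          "uniform_noise", "vonmises_reports")


def _bump_raster(rng, N_E, t_end, centers_deg, rate_peak, width_deg,
                 bg_rate, fade_times=None, drift_deg_per_s=0.0):
    """Poisson raster for one or more Gaussian bumps on the ring."""
    theta = 360.0 * np.arange(1, N_E + 1) / N_E
    dt = 1.0  # ms resolution is plenty for fixtures
    times = np.arange(0.0, t_end, dt)
    sp_t, sp_n = [], []
    centers = np.atleast_1d(np.asarray(centers_deg, dtype=float))
    fades = (np.full(centers.size, np.inf) if fade_times is None
             else np.atleast_1d(np.asarray(fade_times, dtype=float)))
    for ti, t in enumerate(times):
        lam = np.full(N_E, bg_rate / 1000.0)
        for c0, tf in zip(centers, fades):
            if t >= tf:
                continue
            c = c0 + drift_deg_per_s * t / 1000.0
            d = np.abs(theta - c % 360.0)
            d = np.minimum(d, 360.0 - d)
            lam += rate_peak / 1000.0 * np.exp(-d ** 2 / (2 * width_deg ** 2))
        counts = rng.poisson(lam * dt)
        idx = np.repeat(np.arange(N_E), counts)
        if idx.size:
            sp_n.append(idx)
            sp_t.append(np.full(idx.size, t + dt))
    if sp_t:
        return np.concatenate(sp_t), np.concatenate(sp_n)
    return np.empty(0), np.empty(0, dtype=int)


def make_fixture(kind: str, seed: int = 0, **params):
    """Build a synthetic raster / rate map / report sample.

    Returns (data, truth) where ``truth`` is a dict of the generating
    parameters relevant to the assertion.  Kinds:

    - ``stable_bump``: one stationary bump (center, peak rate, width).
    - ``drifting_bump``: bump center moves linearly (drift_deg_per_s).
    - ``fading_bump``: bump vanishes at ``fade_time`` ms.
    - ``merged_bumps``: two stimuli, one shared bump arc.
    - ``uniform_noise``: background spikes only.
    - ``vonmises_reports``: mixture of k clusters of reports (degrees).
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "vonmises_reports":
        k = params.get("k", 4)
        n = params.get("n", 2000)
        kappa = params.get("kappa", 20.0)
        guess_frac = params.get("guess_frac", 0.0)
        centers = params.get("centers")
        if centers is None:
            centers = (180.0 / k + 360.0 * np.arange(k) / k) % 360.0
        centers = np.asarray(centers, dtype=float)
        comp = rng.integers(0, centers.size, n)
        reports = (centers[comp]
                   + np.rad2deg(rng.vonmises(0.0, kappa, n))) % 360.0
        g = rng.random(n) < guess_frac
        reports[g] = rng.uniform(0.0, 360.0, int(g.sum()))
        return reports, dict(centers=centers, k=int(centers.size))

    N_E = params.get("N_E", 512)
    t_end = params.get("t_end", 2000.0)
    bg = params.get("bg_rate", 0.5)
    width = params.get("width_deg", 10.0)
    peak = params.get("rate_peak", 30.0)
    if kind == "uniform_noise":
        t, n = _bump_raster(rng, N_E, t_end, [], peak, width, bg)
        return (t, n), dict(N_E=N_E, t_end=t_end, bg_rate=bg)
    if kind == "stable_bump":
        c = params.get("center_deg", 200.0)
        t, n = _bump_raster(rng, N_E, t_end, [c], peak, width, bg)
        return (t, n), dict(center_deg=c, rate_peak=peak, width_deg=width,
                            N_E=N_E, t_end=t_end)
    if kind == "drifting_bump":
        c = params.get("center_deg", 100.0)
        v = params.get("drift_deg_per_s", 20.0)
        t, n = _bump_raster(rng, N_E, t_end, [c], peak, width, bg,
                            drift_deg_per_s=v)
        end = (c + v * t_end / 1000.0) % 360.0
        return (t, n), dict(center_deg=c, drift_deg_per_s=v,
                            end_center_deg=end, N_E=N_E, t_end=t_end)
    if kind == "fading_bump":
        c = params.get("center_deg", 200.0)
        tf = params.get("fade_time", 1000.0)
        t, n = _bump_raster(rng, N_E, t_end, [c], peak, width, bg,
                            fade_times=[tf])
        return (t, n), dict(center_deg=c, fade_time=tf, N_E=N_E, t_end=t_end)
    # merged_bumps: two stimuli, a single arc between them
    s1 = params.get("stim1_deg", 120.0)
    s2 = params.get("stim2_deg", 150.0)
    shared = (s1 + ((s2 - s1 + 180) % 360 - 180) / 2.0) % 360.0
    t, n = _bump_raster(rng, N_E, t_end, [shared], peak, width, bg)
    return (t, n), dict(stim1_deg=s1, stim2_deg=s2, shared_center=shared,
                        N_E=N_E, t_end=t_end)
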