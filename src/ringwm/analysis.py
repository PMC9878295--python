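"""Statistics of reports, report errors, membrane potentials, and STP maps.

Report errors are circular differences wrapped to [-180, 180) degrees.  The
error histogram is fit with an (unconstrained) Gaussian by least squares,
mirroring the common practice of fitting the linear histogram rather than a
circular likelihood.  Report clustering is quantified by the modes of a von
Mises kernel density estimate; the mode detector thresholds peak prominence
both at a fraction of the density maximum and at a multiple of the
analytic fluctuation level of a uniform-sample KDE, so small samples do not
produce spurious clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.special import i0e

__all__ = [
    "ReportStats",
    "PotentialStats",
    "wrap_error",
    "error_histogram",
    "fit_gaussian_error",
    "count_modes",
    "circular_kde",
    "potential_stats",
    "stp_maps",
    "flank_asymmetry",
    "rayleigh_moment_test",
    "pool_reports",
]


class FitError(RuntimeError):
    """Degenerate histogram; the Gaussian fit is not defined."""


def wrap_error(report, stimulus):
    """Circular difference report - stimulus in degrees, in [-180, 180)."""
    return (np.asarray(report, dtype=float)
            - np.asarray(stimulus, dtype=float) + 180.0) % 360.0 - 180.0


def error_histogram(errors, bin_width: float = 10.0):
    """Density histogram of wrapped errors; integrates to 1 exactly."""
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    dens, edges = np.histogram(errors, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-(x - mu) ** 2 / (2.0 * sigma ** 2))


def fit_gaussian_error(errors, bin_width: float = 10.0):
    """Least-squares Gaussian fit to the error-density histogram.

    Returns ((amp, mu, sigma), SSE).  ``sigma`` is reported positive.
    Raises :class:`FitError` when fewer than two histogram bins are
    occupied (no width information).
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 30:
        raise FitError("need at least 30 errors for a stable fit")
    centers, dens = error_histogram(errors, bin_width)
    if np.count_nonzero(dens) < 2:
        raise FitError("degenerate histogram: fewer than 2 occupied bins")
    mu0 = float(np.clip(np.mean(errors), -90, 90))
    s0 = float(np.std(errors))
    s0 = min(max(s0, bin_width / 2), 120.0)
    p0 = (dens.max(), mu0, s0)
    # sigma is capped at the half-support: wider "Gaussians" are just
    # constants and carry no width information on the circle
    popt, _ = curve_fit(_gauss, centers, dens, p0=p0, maxfev=20000,
                        bounds=([0.0, -180.0, 1e-3],
                                [np.inf, 180.0, 180.0]))
    amp, mu, sigma = popt
    sigma = abs(float(sigma))
    sse = float(np.sum((dens - _gauss(centers, *popt)) ** 2))
    return (float(amp), float(mu), sigma), sse


def circular_kde(angles_deg, kappa: float, grid_step: float = 1.0):
    """von Mises kernel density on a degree grid; normalized to max 1."""
    r = np.deg2rad(np.asarray(angles_deg, dtype=float))
    grid = np.arange(0.0, 360.0, grid_step)
    g = np.deg2rad(grid)
    dens = np.exp(kappa * np.cos(g[:, None] - r[None, :])).sum(axis=1)
    dens /= dens.max()
    return grid, dens


def count_modes(reports_deg, kde_bandwidth: float | None = None,
                prominence_frac: float = 0.2, null_z: float = 3.5):
    """Count clusters in a circular report distribution.

    Modes are local maxima of a von Mises KDE whose prominence exceeds both
    ``prominence_frac`` of the density maximum and ``null_z`` standard
    deviations of the density fluctuation expected from a *uniform* sample
    of the same size (an analytic small-sample guard: for a vM kernel of
    concentration kappa the pointwise relative s.d. of the KDE under
    uniformity is sqrt((I0(2k)/I0(k)^2 - 1)/n)).

    ``kde_bandwidth`` (the kernel concentration kappa) defaults to
    min(50, max(6, n/8)), adapting the resolution to the sample size.
    Returns (count, locations_deg).
    """
    reports = np.asarray(reports_deg, dtype=float)
    n = reports.size
    if n < 2:
        return 0, np.empty(0)
    kappa = kde_bandwidth if kde_bandwidth is not None else \
        min(50.0, max(6.0, n / 8.0))
    grid, dens = circular_kde(reports, kappa)
    ratio = i0e(2 * kappa) / (i0e(kappa) ** 2)   # = I0(2k)/I0(k)^2
    null_sd = np.sqrt(max(ratio - 1.0, 0.0) / n) * dens.mean()
    thresh = max(prominence_frac * dens.max(), null_z * null_sd)
    tiles = np.tile(dens, 3)
    peaks, _ = find_peaks(tiles, prominence=thresh)
    peaks = peaks[(peaks >= dens.size) & (peaks < 2 * dens.size)] - dens.size
    locs = grid[peaks]
    return len(locs), locs


def rayleigh_moment_test(angles_deg, moment: int = 1):
    """Rayleigh uniformity test on the m-th circular moment.

    Tests whether exp(i * m * theta) has nonzero mean resultant; for
    reports clustered at k equally spaced locations the k-th (and its
    multiples') moment concentrates.  Returns (R_bar, p_value).
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float)) * moment
    n = a.size
    R = np.abs(np.mean(np.exp(1j * a)))
    # Rayleigh test with small-sample correction (Zar 1999)
    z = n * R ** 2
    p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4)
                      / (288 * n ** 2))
    return float(R), float(min(max(p, 0.0), 1.0))


@dataclass
class ReportStats:
    """Pooled report/error statistics for one batch."""

    reports: np.ndarray
    stimuli: np.ndarray
    errors: np.ndarray
    bin_width: float
    hist_centers: np.ndarray
    hist_density: np.ndarray
    fit_amp: float = np.nan
    fit_mu: float = np.nan
    fit_sigma: float = np.nan
    sse: float = np.nan
    n_modes: int = 0
    mode_locations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def error_sd(self) -> float:
        return float(np.std(self.errors))


def pool_reports(stimuli_deg, reports_deg, bin_width: float = 10.0,
                 fit: bool = True) -> ReportStats:
    """Pool a batch's reports into error statistics, fit, and mode count."""
    stimuli = np.asarray(stimuli_deg, dtype=float).ravel()
    reports = np.asarray(reports_deg, dtype=float).ravel()
    errors = wrap_error(reports, stimuli)
    centers, dens = error_histogram(errors, bin_width)
    stats = ReportStats(reports=reports, stimuli=stimuli, errors=errors,
                        bin_width=bin_width, hist_centers=centers,
                        hist_density=dens)
    if fit:
        try:
            (amp, mu, sigma), sse = fit_gaussian_error(errors, bin_width)
            stats.fit_amp, stats.fit_mu, stats.fit_sigma = amp, mu, sigma
            stats.sse = sse
        except (FitError, RuntimeError):
            pass
    stats.n_modes, stats.mode_locations = count_modes(reports)
    return stats


# ---------------------------------------------------------------------------
# membrane-potential and STP spatiotemporal summaries
# ---------------------------------------------------------------------------

@dataclass
class PotentialStats:
    """Per-E-neuron mean and s.d. of V over the final analysis window."""

    V_mean: np.ndarray
    V_std: np.ndarray
    window: float


def potential_stats(V_samples: np.ndarray, sample_times: np.ndarray,
                    window_last: float = 1000.0) -> PotentialStats:
    """Mean/s.d. of each E neuron's membrane potential over the last window.

    ``V_samples``: (N_E, n_samples) mV on the 1 ms sampling grid of one
    trial.
    """
    sel = sample_times > sample_times[-1] - window_last
    if sel.sum() < 2:
        raise ValueError("potential_stats: trajectory shorter than window")
    seg = np.asarray(V_samples, dtype=float)[:, sel]
    return PotentialStats(V_mean=seg.mean(axis=1), V_std=seg.std(axis=1),
                          window=window_last)


def bump_membership(rates_end: np.ndarray, theta: np.ndarray,
                    baseline: float = 2.0):
    """(inside, outside) index arrays relative to the final activity bump.

    Inside = within +-2 half-widths of the decoded bump center, where the
    half-width is that of the supra-baseline arc; with no supra-baseline
    activity everything is outside.
    """
    mask = rates_end > baseline
    if not mask.any():
        return np.empty(0, np.intp), np.arange(theta.size)
    z = np.sum(rates_end[mask] * np.exp(1j * theta[mask]))
    center = np.angle(z)
    half_width = max(mask.mean() * np.pi, 2 * np.pi / theta.size)
    # cap the membership radius so a wide plateau still leaves an outside
    radius = min(2 * half_width, 0.55 * np.pi)
    d = np.abs(np.angle(np.exp(1j * (theta - center))))
    inside = np.flatnonzero(d <= radius)
    outside = np.flatnonzero(d > radius)
    return inside, outside


def stp_maps(u_samples: np.ndarray, x_samples: np.ndarray):
    """u, x, and the overall plasticity u*x on the sampling grid."""
    ux = np.asarray(u_samples, dtype=float) * np.asarray(x_samples,
                                                         dtype=float)
    return np.asarray(u_samples), np.asarray(x_samples), ux


def flank_asymmetry(ux_map: np.ndarray, theta: np.ndarray, cue_deg: float,
                    U: float, flank_deg: float = 45.0,
                    inner_deg: float = 0.0):
    """Difference in mean u*x depression between the two flanks of the cue.

    Depression is U - u*x (positive where transmission is weakened).  The
    index is mean depression on the counterclockwise flank (cue, cue+flank]
    minus the clockwise flank [cue-flank, cue), averaged over time; a
    positive value means the counterclockwise side is more depressed, i.e.
    activity has spread toward larger angles.
    """
    cue = np.deg2rad(cue_deg)
    fl = np.deg2rad(flank_deg)
    inner = np.deg2rad(inner_deg)
    d = np.angle(np.exp(1j * (theta - cue)))  # signed, (-pi, pi]
    ccw = (d > inner) & (d <= fl)
    cw = (d < -inner) & (d >= -fl)
    dep = U - np.asarray(ux_map, dtype=float)
    return float(dep[ccw].mean() - dep[cw].mean())
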