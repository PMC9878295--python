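"""Panel plots of batch outputs: report/error distributions, V stats, STP maps."""

from __future__ import annotations

import numpy as np

from .analysis import PotentialStats, ReportStats, circular_kde


def plot_report_panels(stats: ReportStats, axes=None):
    """Two panels: error histogram with Gaussian fit; report distribution.

    Mirrors the standard layout: left, the density histogram of wrapped
    report errors with the fitted Gaussian overlaid; right, the report
    histogram with a smoothed (KDE) curve and the uniform stimulus level.
    """
    import matplotlib.pyplot as plt
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    ax_err, ax_rep = axes
    ax_err.bar(stats.hist_centers, stats.hist_density,
               width=stats.bin_width, color="C0", alpha=0.7,
               label="model error")
    if np.isfinite(stats.fit_sigma):
        e = np.linspace(-180, 180, 721)
        fit = stats.fit_amp * np.exp(-(e - stats.fit_mu) ** 2
                                     / (2 * stats.fit_sigma ** 2))
        ax_err.plot(e, np.clip(fit, 0, None), "r-",
                    label=f"Gaussian fit (sigma={stats.fit_sigma:.1f} deg)")
    ax_err.set_xlabel("report error (deg)")
    ax_err.set_ylabel("density")
    ax_err.legend(fontsize=8)

    ax_rep.hist(stats.reports, bins=np.arange(0, 361, 5), density=True,
                color="C0", alpha=0.7, label="reports")
    grid, dens = circular_kde(stats.reports,
                              min(50.0, max(6.0, stats.reports.size / 8.0)))
    scale = 1.0 / 360.0 / max(dens.mean(), 1e-12)
    ax_rep.plot(grid, dens * scale, "r-", label="smoothed")
    ax_rep.axhline(1.0 / 360.0, color="g", ls="--", label="stimulus (uniform)")
    ax_rep.set_xlabel("report (deg)")
    ax_rep.legend(fontsize=8)
    return axes


def plot_potential_stats(with_stp: PotentialStats, without_stp: PotentialStats,
                         theta_deg, axes=None):
    """Mean and s.d. of V per E neuron, with vs. without plasticity."""
    import matplotlib.pyplot as plt
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, attr, label in ((axes[0], "V_mean", "mean V (mV)"),
                            (axes[1], "V_std", "s.d. of V (mV)")):
        ax.plot(theta_deg, getattr(with_stp, attr), "b-", lw=0.8,
                label="with STP")
        ax.plot(theta_deg, getattr(without_stp, attr), "r-", lw=0.8,
                label="without STP")
        ax.set_xlabel("preferred color (deg)")
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
    return axes


def plot_stp_maps(u_map, x_map, sample_times, theta_deg, axes=None):
    """Spatiotemporal maps of u (top), x (middle), and u*x (bottom)."""
    import matplotlib.pyplot as plt
    if axes is None:
        _, axes = plt.subplots(3, 1, figsize=(6, 7), sharex=True)
    extent = [sample_times[0], sample_times[-1],
              theta_deg[0], theta_deg[-1]]
    for ax, m, label in ((axes[0], u_map, "u"),
                         (axes[1], x_map, "x"),
                         (axes[2], np.asarray(u_map) * np.asarray(x_map),
                          "u*x")):
        im = ax.imshow(m, aspect="auto", origin="lower", extent=extent,
                       cmap="viridis")
        ax.set_ylabel(f"{label}: color (deg)")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
    axes[-1].set_xlabel("time (ms)")
    return axes
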