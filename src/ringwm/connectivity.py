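"""Heterogeneous ring connectivity.

E neurons sit on a ring at evenly spaced preferred colors theta_i.  The E->E
synaptic footprint is a Gaussian of the circular preference difference on a
uniform baseline,

    W(dtheta_{j,i}) = J_i^- + (J_i^+ - J_i^-) exp(-dtheta^2 / 2 sigma_i^2),

normalized so that the mean footprint onto every postsynaptic neuron is 1:
(1/2pi) integral_0^{2pi} W d(theta_j) = 1.  Heterogeneity enters through a
periodic amplitude profile y_i with ``n_peaks`` equally spaced maxima:
neurons at the peaks get a larger amplitude J_i^+ and, through the shared
normalization, a narrower width sigma_i.  The baseline J^- is shared by all
neurons.  Couplings involving I neurons are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .config import ConfigError, ConnectivityParams

__all__ = [
    "HeterogeneousProfile",
    "preferred_angles",
    "heterogeneity_profile",
    "amplitude_profile",
    "baseline_coupling",
    "width_profile",
    "footprint_matrix",
    "build_profile",
    "circular_distance",
    "save_profile",
    "load_profile",
]


def circular_distance(a, b):
    """Unsigned circular distance between angles (radians), in [0, pi]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % (2 * np.pi)
    return np.where(d > np.pi, 2 * np.pi - d, d)


def preferred_angles(N_E: int) -> np.ndarray:
    """Preferred colors theta_i = 2*pi*i/N for i = 1..N (so 0 < theta <= 2pi)."""
    if N_E < 1:
        raise ConfigError("preferred_angles: N_E must be >= 1")
    return 2 * np.pi * np.arange(1, N_E + 1) / N_E


def heterogeneity_profile(N_E: int, b: float, S_N: float = 10.0,
                          n_peaks: int = 4) -> np.ndarray:
    """Periodic amplitude profile y_i with ``n_peaks`` equally spaced maxima.

    y_i = 1 - (1/b) * [1 - exp(-d_i^2 / S_N^2) / sqrt(2 pi)]

    where d_i is the index distance from neuron i (1-based) to the nearest
    peak.  Peaks sit at indices N/(2p) + k*N/p, i.e. at angles
    pi/p + 2*pi*k/p (45/135/225/315 deg for p=4).  As b -> inf, y -> 1
    uniformly (homogeneous ring).
    """
    if b <= 0:
        raise ConfigError("heterogeneity_profile: b must be > 0")
    if n_peaks < 1:
        raise ConfigError("heterogeneity_profile: n_peaks must be >= 1")
    i = np.arange(1, N_E + 1, dtype=float)
    cell = N_E / n_peaks
    # signed index distance to the nearest peak (peaks at cell/2 + k*cell)
    d = i % cell - cell / 2.0
    return 1.0 - (1.0 / b) * (1.0 - np.exp(-(d ** 2) / S_N ** 2)
                              / np.sqrt(2 * np.pi))


def amplitude_profile(y: np.ndarray, J_bar: float) -> np.ndarray:
    """Footprint amplitudes J_i^+ = J_bar * N * y_i / sum_j y_j (mean = J_bar)."""
    y = np.asarray(y, dtype=float)
    total = y.sum()
    if not total > 0:
        raise ConfigError("amplitude_profile: sum of y must be > 0")
    return J_bar * y.size * y / total


def _footprint_mean_coeff(sigma: float) -> float:
    """c(sigma) = (sigma/sqrt(2pi)) * erf(pi / (sqrt(2) sigma)).

    Mean over the circle of a unit-height Gaussian of width sigma centered
    anywhere: (1/2pi) * integral_{-pi}^{pi} exp(-u^2/2 sigma^2) du.
    """
    return sigma / np.sqrt(2 * np.pi) * erf(np.pi / (np.sqrt(2) * sigma))


def baseline_coupling(J_bar: float, sigma_bar: float) -> float:
    """Shared baseline J^- from the footprint normalization.

    Solving (1/2pi) int_{-pi}^{pi} [J^- + (J_bar - J^-) e^{-u^2/2 sigma_bar^2}] du = 1
    gives J^- = (1 - J_bar c) / (1 - c) with c = _footprint_mean_coeff(sigma_bar).
    """
    if not (0 < sigma_bar < np.pi):
        raise ConfigError("baseline_coupling: sigma_bar must be in (0, pi) rad")
    c = _footprint_mean_coeff(sigma_bar)
    J_minus = (1.0 - J_bar * c) / (1.0 - c)
    if J_minus <= 0:
        raise ConfigError(
            f"baseline_coupling: J_bar={J_bar}, sigma_bar={sigma_bar} rad "
            f"yield J^-={J_minus:.4g} <= 0")
    return J_minus


def width_profile(J_plus: np.ndarray, J_minus: float) -> np.ndarray:
    """Per-neuron footprint widths sigma_i (radians) from the normalization.

    Each sigma_i solves c(sigma_i) = (1 - J^-) / (J_i^+ - J^-); a larger
    amplitude J_i^+ forces a narrower footprint.
    """
    J_plus = np.asarray(J_plus, dtype=float)
    lo, hi = 1e-3, np.pi
    c_lo, c_hi = _footprint_mean_coeff(lo), _footprint_mean_coeff(hi)
    sigma = np.empty_like(J_plus)
    # cache roots: identical amplitudes share a width
    seen: dict[float, float] = {}
    for k, jp in enumerate(J_plus):
        if jp in seen:
            sigma[k] = seen[jp]
            continue
        if not jp > 1.0 or not J_minus < 1.0:
            raise ConfigError(
                f"width_profile: neuron {k + 1}: need J_i^+ > 1 > J^- "
                f"(got J_i^+={jp:.4g}, J^-={J_minus:.4g})")
        target = (1.0 - J_minus) / (jp - J_minus)
        if not (c_lo <= target <= c_hi):
            raise ConfigError(
                f"width_profile: neuron {k + 1}: no width in "
                f"({lo}, pi) rad solves the normalization (target {target:.4g})")
        sigma[k] = seen[jp] = brentq(
            lambda s: _footprint_mean_coeff(s) - target, lo, hi,
            xtol=1e-12, rtol=8.9e-16)
    return sigma


@dataclass
class HeterogeneousProfile:
    """Per-neuron connectivity profile plus the dense E->E footprint matrix.

    ``W[j, i]`` is the footprint from presynaptic neuron j onto postsynaptic
    neuron i.  The synaptic conductance used by the simulator is
    G_EE_NMDA * W[j, i] / N_E (per-contact scaling, so total recurrent drive
    is independent of N at fixed mean W).
    """

    theta: np.ndarray     # preferred angles, radians, (N_E,)
    y: np.ndarray         # heterogeneity profile, (N_E,)
    J_plus: np.ndarray    # footprint amplitudes, (N_E,)
    J_minus: float        # shared baseline
    sigma_i: np.ndarray   # footprint widths, radians, (N_E,)
    W: np.ndarray         # footprint matrix, (N_E, N_E)

    @property
    def N_E(self) -> int:
        return self.theta.size

    def peak_angles_deg(self, n_peaks: int) -> np.ndarray:
        """Angles (degrees) of the configured heterogeneity peaks."""
        return (180.0 / n_peaks + 360.0 * np.arange(n_peaks) / n_peaks) % 360.0


def footprint_matrix(theta: np.ndarray, J_plus: np.ndarray, J_minus: float,
                     sigma_i: np.ndarray) -> np.ndarray:
    """Dense footprint matrix W[j, i] over the circular preference distance."""
    dtheta = circular_distance(theta[:, None], theta[None, :])
    return J_minus + (J_plus[None, :] - J_minus) * np.exp(
        -(dtheta ** 2) / (2 * sigma_i[None, :] ** 2))


def build_profile(params: ConnectivityParams) -> HeterogeneousProfile:
    """Construct the full heterogeneous profile from connectivity parameters."""
    theta = preferred_angles(params.N_E)
    y = heterogeneity_profile(params.N_E, params.b, params.S_N, params.n_peaks)
    J_plus = amplitude_profile(y, params.J_bar)
    J_minus = baseline_coupling(params.J_bar, params.sigma_bar)
    if np.any(J_plus <= J_minus):
        raise ConfigError(
            "build_profile: some J_i^+ <= J^-; heterogeneity too strong for "
            f"J_bar={params.J_bar}, sigma_bar={params.sigma_bar_deg} deg, "
            f"b={params.b}")
    sigma_i = width_profile(J_plus, J_minus)
    W = footprint_matrix(theta, J_plus, J_minus, sigma_i)
    return HeterogeneousProfile(theta=theta, y=y, J_plus=J_plus,
                                J_minus=J_minus, sigma_i=sigma_i, W=W)


# ---- export / import ------------------------------------------------------

def save_profile(profile: HeterogeneousProfile, array_path, table_path=None,
                 params: ConnectivityParams | None = None) -> None:
    """Write the profile as a compressed array archive plus a text table."""
    meta = {}
    if params is not None:
        meta = {f"param_{k}": v for k, v in vars(params).items()}
    np.savez_compressed(array_path, theta=profile.theta, y=profile.y,
                        J_plus=profile.J_plus,
                        J_minus=np.array(profile.J_minus),
                        sigma_i=profile.sigma_i, W=profile.W, **meta)
    if table_path is not None:
        pd.DataFrame({
            "neuron_index": np.arange(1, profile.N_E + 1),
            "theta_deg": np.rad2deg(profile.theta),
            "y": profile.y,
            "J_plus": profile.J_plus,
            "sigma_i_deg": np.rad2deg(profile.sigma_i),
        }).to_csv(table_path, index=False)


def load_profile(array_path) -> HeterogeneousProfile:
    with np.load(array_path) as data:
        return HeterogeneousProfile(
            theta=data["theta"], y=data["y"], J_plus=data["J_plus"],
            J_minus=float(data["J_minus"]), sigma_i=data["sigma_i"],
            W=data["W"])
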