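"""Drift-diffusion reference model of the memory trace.

A single memory trace theta evolves on the circle as

    d theta = beta * G(theta) dt + sigma * dW,

where the drift G is half the derivative of a 12-component von Mises
mixture density,

    G(theta) = sum_j (1/2) w_j d/dtheta phi(theta; mu_j, kappa),
    mu_j = 2*pi*j/12,

so trajectories drift uphill toward the mixture's modes (discrete
attractors) while diffusing.  The stochastic integral is taken in the
Stratonovich sense and integrated with the Euler-Heun predictor-corrector.
After the delay the trace is reported, replaced by a uniform random guess
with probability lam (guess rate); the swap rate is zero for single-item
trials.  The mixture's width parameter 2*pi/12 is interpreted as a
circular-s.d.-like width s with kappa = 1/s^2 (a config option allows
kappa = 2*pi/12 directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

__all__ = [
    "SDEParams",
    "FITTED_WEIGHTS",
    "BOOSTED_WEIGHTS",
    "vm_mixture_density",
    "drift",
    "euler_heun_step",
    "run_sde_batch",
]

# 12 fitted mixture weights (dimensionless; sum = 0.9997)
FITTED_WEIGHTS = np.array([6.26, 8.22, 9.75, 7.89, 7.48, 10.28,
                           7.23, 7.75, 9.62, 7.74, 6.48, 11.27]) * 1e-2
# variant with a fixed value added at the four largest components
BOOSTED_WEIGHTS = np.array([6.26, 8.22, 59.75, 7.89, 7.48, 60.28,
                            7.23, 7.75, 59.62, 7.74, 6.48, 61.27]) * 1e-2


@dataclass
class SDEParams:
    """Drift-diffusion parameters (fitted load-1 values as defaults)."""

    beta: float = 0.0917          # drift gain, 1/time
    sigma: float = 3.637e-4       # noise scale, rad/sqrt(time)
    w: np.ndarray = field(default_factory=lambda: FITTED_WEIGHTS.copy())
    width: float = 2 * np.pi / 12  # component width parameter, rad
    width_is_kappa: bool = False   # True: use width directly as kappa
    lam: float = 0.0               # guess rate
    swap: float = 0.0              # swap rate (0 for load 1)
    dt: float = 1.0                # integration step, time units
    T: float = 3000.0              # delay duration, time units

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.size != 12:
            raise ValueError("SDEParams: w must have 12 components")
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.swap <= 1.0):
            raise ValueError("SDEParams: lam and swap must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("SDEParams: dt must be > 0")

    @property
    def kappa(self) -> float:
        return self.width if self.width_is_kappa else 1.0 / self.width ** 2

    @property
    def mu(self) -> np.ndarray:
        return 2 * np.pi * np.arange(1, 13) / 12


def vm_mixture_density(theta, params: SDEParams):
    """Weighted von Mises mixture density sum_j w_j phi(theta; mu_j, kappa)."""
    th = np.asarray(theta, dtype=float)
    k = params.kappa
    norm = 1.0 / (2 * np.pi * i0(k))
    return (params.w[None, :]
            * norm * np.exp(k * np.cos(th[..., None] - params.mu[None, :]))
            ).sum(axis=-1)


def drift(theta, params: SDEParams):
    """Drift G(theta) = sum_j (1/2) w_j phi'(theta; mu_j, kappa).

    2*pi-periodic and conservative: its integral over the circle is 0, so
    the stationary density of the noiseless flow concentrates at the
    mixture's modes.
    """
    th = np.asarray(theta, dtype=float)
    k = params.kappa
    norm = 1.0 / (2 * np.pi * i0(k))
    dphi = (-k * np.sin(th[..., None] - params.mu[None, :])
            * norm * np.exp(k * np.cos(th[..., None] - params.mu[None, :])))
    return 0.5 * (params.w[None, :] * dphi).sum(axis=-1)


def euler_heun_step(theta, params: SDEParams, rng: np.random.Generator,
                    dW=None):
    """One Euler-Heun (Stratonovich) step; theta wrapped to [0, 2*pi).

    With sigma = 0 this reduces to the deterministic Heun step.
    """
    th = np.asarray(theta, dtype=float)
    dt = params.dt
    if dW is None:
        dW = rng.normal(0.0, np.sqrt(dt), size=th.shape)
    b = params.beta
    g1 = b * drift(th, params)
    pred = th + g1 * dt + params.sigma * dW
    g2 = b * drift(pred, params)
    return (th + 0.5 * (g1 + g2) * dt + params.sigma * dW) % (2 * np.pi)


def run_sde_batch(params: SDEParams, n_paths: int, seed: int = 0,
                  theta0=None, record_every: int | None = None):
    """Evolve a batch of memory traces and produce reports and errors.

    Initial angles are uniform unless ``theta0`` (radians) is given.  After
    T time units each trace is reported; with probability lam the report is
    replaced by a uniform random guess.  Returns a dict with stimuli,
    reports, errors (all degrees) and optionally the recorded trajectory.
    """
    if n_paths < 1:
        raise ValueError("run_sde_batch: n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    if theta0 is None:
        th = rng.uniform(0.0, 2 * np.pi, n_paths)
    else:
        th = np.broadcast_to(np.asarray(theta0, dtype=float),
                             (n_paths,)).copy()
    stimuli = th.copy()
    n_steps = int(round(params.T / params.dt))
    traj = [] if record_every else None
    for k in range(n_steps):
        th = euler_heun_step(th, params, rng)
        if record_every and (k + 1) % record_every == 0:
            traj.append(th.copy())
    reports = th.copy()
    guesses = rng.random(n_paths) < params.lam
    reports[guesses] = rng.uniform(0.0, 2 * np.pi, int(guesses.sum()))
    stim_deg = np.rad2deg(stimuli) % 360.0
    rep_deg = np.rad2deg(reports) % 360.0
    errors = (rep_deg - stim_deg + 180.0) % 360.0 - 180.0
    out = dict(stimuli=stim_deg, reports=rep_deg, errors=errors)
    if traj is not None:
        out["trajectory"] = np.rad2deg(np.array(traj)) % 360.0
    return out
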