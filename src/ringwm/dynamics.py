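"""Coupled LIF membrane, synaptic-gating, and short-term-plasticity dynamics.

The network is integrated with a fixed-step Heun (RK2) scheme:

* membrane potentials and the nonlinear NMDA gating ODE
  ds/dt = -s/tau_S + alpha_S * y * (1 - s) go through the two-stage Heun
  update (the E->E recurrent sum is re-evaluated at both stages);
* all purely linear decays (background AMPA gating, GABA gating, the NMDA
  rise variable y, and the STP variables u, x between spikes) use exact
  exponential updates;
* threshold crossings are detected once per full step; reset, refractory
  clamping, and all spike-triggered jumps (STP, gating increments) are
  applied at the end of the step and take effect from the next step.

Currents follow the convention that positive current depolarizes:
I = -(V - V_rev) * g * s.  The NMDA current is attenuated by the
voltage-dependent Mg2+ block 1 + [Mg] * exp(-0.062 V) / 3.57.

The hot path is vectorized over a *batch* of trials: state variables are
(n_neurons, n_trials) arrays, E and I populations are stacked so per-neuron
parameters broadcast as column vectors, and each Heun stage costs one BLAS
matrix product for the E->E recurrent sum.  The batched state is float32
(a documented numerical choice: per-step increments are ~1e-4 relative, far
above float32 resolution); single-step utilities default to float64.
Per-trial background noise comes from independent, counter-seeded streams,
so any trial is bit-for-bit reproducible regardless of its batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import NetworkConfig, STPParams, SynapseParams
from .connectivity import HeterogeneousProfile

__all__ = [
    "NetworkState",
    "SimulationResult",
    "NumericalError",
    "mg_block",
    "total_current",
    "stp_on_spike",
    "stp_decay",
    "nmda_gating_step",
    "background_poisson",
    "make_state",
    "rk2_step",
    "simulate_batch",
]


class NumericalError(RuntimeError):
    """Non-finite state encountered during integration."""


def mg_block(V, Mg: float = 1.0):
    """Voltage-dependent magnesium-block divisor of the NMDA current."""
    return 1.0 + Mg * np.exp(-0.062 * np.asarray(V)) / 3.57


# ---------------------------------------------------------------------------
# elementary operations (single-step views of the kernel's update rules)
# ---------------------------------------------------------------------------

def stp_on_spike(u, x, U: float, pre_jump_u: bool = False):
    """Spike-triggered STP update.

    Utilization facilitates first, u' = u + U*(1-u); resources then deplete
    by the transmitted drive.  By default the drive uses the post-jump
    utilization (drive = u' * x); ``pre_jump_u=True`` selects the
    pre-facilitation convention (drive = u * x).
    """
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    u_new = u + U * (1.0 - u)
    drive = (u if pre_jump_u else u_new) * x
    return u_new, x - drive, drive


def stp_decay(u, x, dt: float, stp: STPParams):
    """Exact inter-spike relaxation of (u, x) toward the fixed point (U, 1)."""
    fu = np.exp(-dt / stp.tau_u)
    fx = np.exp(-dt / stp.tau_x)
    return stp.U + (u - stp.U) * fu, 1.0 + (x - 1.0) * fx


def nmda_gating_step(s, y, spike_drives, dt: float, syn: SynapseParams):
    """One step of the second-order NMDA gating dynamics.

    ``y`` decays exponentially (tau_y) and jumps by the per-spike drive u*x
    (or 1 with plasticity disabled); ``s`` follows the saturating ODE via a
    Heun step with y evaluated consistently at both stages.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    k1 = -s / syn.tau_NMDA + syn.alpha_S * y * (1.0 - s)
    s_pred = s + dt * k1
    y_end = y * np.exp(-dt / syn.tau_y)
    k2 = -s_pred / syn.tau_NMDA + syn.alpha_S * y_end * (1.0 - s_pred)
    return s + 0.5 * dt * (k1 + k2), y_end + np.asarray(spike_drives, dtype=float)


# Poisson CDF truncation: P(X > 8 | lam <= 0.05) < 1e-18
_POISSON_KMAX = 8


def _poisson_cdf(lam: float, kmax: int) -> np.ndarray:
    pmf = np.empty(kmax)
    pmf[0] = np.exp(-lam)
    for k in range(1, kmax):
        pmf[k] = pmf[k - 1] * lam / k
    return np.cumsum(pmf)


def background_poisson(rate: float, dt: float, rng: np.random.Generator,
                       size) -> np.ndarray:
    """Poisson spike counts per neuron for one step (mean rate*dt each).

    Small means are sampled by inverse-CDF on a single uniform draw
    (exact to double precision up to 8 events for rate*dt <= 0.05);
    larger means use the generator's Poisson sampler.
    """
    lam = rate * dt
    if lam < 0:
        raise ValueError("background_poisson: rate and dt must be >= 0")
    if lam == 0:
        return np.zeros(size, dtype=np.uint8)
    if lam > 0.05:
        return rng.poisson(lam, size=size)
    u = rng.random(size)
    counts = np.zeros(size, dtype=np.uint8)
    for p in _poisson_cdf(lam, _POISSON_KMAX):
        counts += u > p
    return counts


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """All per-neuron state variables at one instant, for a trial batch.

    E and I populations are stacked: rows 0..N_E-1 of ``V``, ``refr``,
    ``s_AMPA_n`` are E neurons, the rest I neurons.  ``n_trials`` may be 1.
    """

    N_E: int
    V: np.ndarray         # membrane potentials, mV, (N_E + N_I, B)
    refr: np.ndarray      # remaining refractory steps, int16
    s_AMPA_n: np.ndarray  # background AMPA gating, per neuron
    s_NMDA: np.ndarray    # NMDA gating, per presynaptic E neuron, (N_E, B)
    y_NMDA: np.ndarray    # NMDA rise variable, (N_E, B)
    s_GABA: np.ndarray    # GABA gating, per presynaptic I neuron, (N_I, B)
    u: np.ndarray         # STP utilization, (N_E, B)
    x: np.ndarray         # STP resources, (N_E, B)
    t: float = 0.0        # current time, ms

    @property
    def V_E(self):
        return self.V[:self.N_E]

    @property
    def V_I(self):
        return self.V[self.N_E:]

    @property
    def n_trials(self) -> int:
        return self.V.shape[1]


def make_state(cfg: NetworkConfig, n_trials: int = 1,
               dtype=np.float64) -> NetworkState:
    """Fresh resting state: V = V_L, gating at zero, STP at its fixed point."""
    NE, NI = cfg.connectivity.N_E, cfg.connectivity.N_I
    N = NE + NI
    V = np.empty((N, n_trials), dtype)
    V[:NE] = cfg.neuron_E.V_L
    V[NE:] = cfg.neuron_I.V_L
    return NetworkState(
        N_E=NE, V=V,
        refr=np.zeros((N, n_trials), np.int16),
        s_AMPA_n=np.zeros((N, n_trials), dtype),
        s_NMDA=np.zeros((NE, n_trials), dtype),
        y_NMDA=np.zeros((NE, n_trials), dtype),
        s_GABA=np.zeros((NI, n_trials), dtype),
        u=np.full((NE, n_trials), cfg.stp.U, dtype),
        x=np.ones((NE, n_trials), dtype), t=0.0)


@dataclass
class SimulationResult:
    """Spike data and optional state samples from a batch of trials."""

    n_trials: int
    t_end: float
    dt: float
    spike_t: np.ndarray       # E spike times, ms
    spike_neuron: np.ndarray  # E neuron index (0-based)
    spike_trial: np.ndarray   # trial index within the batch
    sample_times: np.ndarray | None = None
    V_samples: np.ndarray | None = None   # (N_E, n_samples, B) float32
    u_samples: np.ndarray | None = None
    x_samples: np.ndarray | None = None
    spike_t_I: np.ndarray | None = None
    spike_neuron_I: np.ndarray | None = None
    spike_trial_I: np.ndarray | None = None

    def trial_raster(self, k: int):
        """(times_ms, neuron_indices) of E spikes for trial k."""
        m = self.spike_trial == k
        return self.spike_t[m], self.spike_neuron[m]


# ---------------------------------------------------------------------------
# the step kernel
# ---------------------------------------------------------------------------

class _Kernel:
    """Precomputed constants + the Heun/event update for a trial batch."""

    def __init__(self, cfg: NetworkConfig, profile: HeterogeneousProfile,
                 dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        self.dtype = dtype
        con, syn = cfg.connectivity, cfg.synapse
        dt = cfg.sim.dt
        self.dt = dt
        NE, NI = con.N_E, con.N_I
        self.NE, self.NI = NE, NI
        N = NE + NI
        # contraction matrix: row i = presynaptic weights onto postsynaptic i.
        # With footprint_side="pre", the footprint profile (J_j+, sigma_j)
        # belongs to the presynaptic neuron j (its outgoing weights sum to
        # 1), so the weight j->i is W[i, j]; with "post" it is W[j, i].
        self.WT = np.ascontiguousarray(
            profile.W if con.footprint_side == "pre" else profile.W.T,
            dtype=dtype)
        # per-contact conductances in uS (configs are total nS)
        self.g_EE = con.G_EE_NMDA * 1e-3 / NE
        self.g_EI = con.G_EI_NMDA * 1e-3 / NE
        g_IE = con.G_IE_GABA * 1e-3 / NI
        g_II = con.G_II_GABA * 1e-3 / NI

        def col(vE, vI):
            out = np.empty((N, 1), dtype)
            out[:NE] = vE
            out[NE:] = vI
            return out

        nE, nI = cfg.neuron_E, cfg.neuron_I
        self.g_L = col(nE.g_L, nI.g_L)
        self.inv_C = col(1.0 / nE.C_m, 1.0 / nI.C_m)
        self.V_L = col(nE.V_L, nI.V_L)
        self.V_th = col(nE.V_th, nI.V_th)
        self.V_res = col(nE.V_res, nI.V_res)
        self.g_AMPA = col(syn.g_AMPA_E * 1e-3, syn.g_AMPA_I * 1e-3)
        self.c_GABA = col(g_IE, g_II)
        self.n_ref = np.empty((N, 1), np.int16)
        self.n_ref[:NE] = max(1, int(round(nE.tau_ref / dt)))
        self.n_ref[NE:] = max(1, int(round(nI.tau_ref / dt)))
        # exact decay factors
        self.f_AMPA = np.exp(-dt / syn.tau_AMPA)
        self.f_GABA = np.exp(-dt / syn.tau_GABA)
        self.f_y = np.exp(-dt / syn.tau_y)
        self.f_u = np.exp(-dt / cfg.stp.tau_u)
        self.f_x = np.exp(-dt / cfg.stp.tau_x)
        self.mg_c = syn.Mg / 3.57
        self.V_Erev = syn.V_E
        self.V_Irev = syn.V_I

    def _buffers(self, B: int):
        """Preallocated work arrays for a batch width B."""
        if getattr(self, "_buf_B", None) == B:
            return self._buf
        NE, N = self.NE, self.NE + self.NI
        dt_ = self.dtype
        self._buf = dict(
            k1s=np.empty((NE, B), dt_), k2s=np.empty((NE, B), dt_),
            sN_p=np.empty((NE, B), dt_),
            G_in=np.empty((NE, 2 * B), dt_), G_out=np.empty((NE, 2 * B), dt_),
            dV1=np.empty((N, B), dt_), dV2=np.empty((N, B), dt_),
            t1=np.empty((N, B), dt_), t2=np.empty((N, B), dt_),
            nm=np.empty((N, B), dt_), Vp=np.empty((N, B), dt_),
            tE=np.empty((NE, B), dt_),
        )
        self._buf_B = B
        return self._buf

    def _dV(self, V, rec, sum_N, sum_G, s_AMPA, I_e, out, t1, t2, nm):
        """Membrane derivative (mV/ms) for the stacked populations, into out."""
        NE = self.NE
        # Mg block divisor
        np.multiply(V, -0.062, out=t1)
        np.exp(t1, out=t1)
        t1 *= self.mg_c
        t1 += 1.0
        # excitatory conductance: NMDA (blocked) + background AMPA
        np.multiply(rec, self.g_EE, out=nm[:NE])
        np.multiply(sum_N[None, :], self.g_EI, out=nm[NE:])
        nm /= t1
        np.multiply(s_AMPA, self.g_AMPA, out=t2)
        nm += t2
        np.subtract(self.V_Erev, V, out=out)
        out *= nm
        # GABA
        np.subtract(self.V_Irev, V, out=t2)
        t2 *= sum_G[None, :]
        t2 *= self.c_GABA
        out += t2
        if I_e is not None:
            out[:NE] += I_e
        # leak, capacitance
        np.subtract(self.V_L, V, out=t2)
        t2 *= self.g_L
        out += t2
        out *= self.inv_C
        return out

    def step(self, st: NetworkState, counts, I_e=None):
        """Advance the batch by one full step (Heun + threshold + events).

        ``counts``: background Poisson arrival counts, (N_E + N_I, B) or
        None.  Returns boolean spike arrays (E, I).
        """
        dt = self.dt
        stp = self.cfg.stp
        syn = self.cfg.synapse
        NE = self.NE
        B = st.V.shape[1]
        bf = self._buffers(B)
        k1s, k2s, sN_p = bf["k1s"], bf["k2s"], bf["sN_p"]
        sN, y = st.s_NMDA, st.y_NMDA
        inv_tauS = 1.0 / syn.tau_NMDA

        # NMDA gating derivatives and predictor (independent of V)
        np.subtract(1.0, sN, out=k1s)
        k1s *= y
        k1s *= syn.alpha_S
        np.multiply(sN, inv_tauS, out=bf["tE"])
        k1s -= bf["tE"]
        np.multiply(k1s, dt, out=sN_p)
        sN_p += sN

        # one stacked BLAS product covers both Heun stages
        G_in, G_out = bf["G_in"], bf["G_out"]
        G_in[:, :B] = sN
        G_in[:, B:] = sN_p
        np.matmul(self.WT, G_in, out=G_out)
        rec1 = G_out[:, :B]
        rec2 = G_out[:, B:]
        sum_N1 = sN.sum(axis=0)
        sum_N2 = sN_p.sum(axis=0)
        sum_G1 = st.s_GABA.sum(axis=0)
        sum_G2 = sum_G1 * self.f_GABA

        # stage 1
        dV1 = self._dV(st.V, rec1, sum_N1, sum_G1, st.s_AMPA_n, I_e,
                       bf["dV1"], bf["t1"], bf["t2"], bf["nm"])

        # exact linear decays to end of step
        st.s_AMPA_n *= self.f_AMPA
        st.s_GABA *= self.f_GABA
        y *= self.f_y

        # stage 2 at predictor state
        V_p = bf["Vp"]
        np.multiply(dV1, dt, out=V_p)
        V_p += st.V
        np.subtract(1.0, sN_p, out=k2s)
        k2s *= y
        k2s *= syn.alpha_S
        np.multiply(sN_p, inv_tauS, out=bf["tE"])
        k2s -= bf["tE"]
        dV2 = self._dV(V_p, rec2, sum_N2, sum_G2, st.s_AMPA_n, I_e,
                       bf["dV2"], bf["t1"], bf["t2"], bf["nm"])

        # corrector
        dV1 += dV2
        dV1 *= 0.5 * dt
        st.V += dV1
        k1s += k2s
        k1s *= 0.5 * dt
        sN += k1s
        if stp.enabled:
            st.u += (self.f_u - 1.0) * (st.u - stp.U)
            st.x += (self.f_x - 1.0) * (st.x - 1.0)

        # refractory clamp (dV/dt forced to 0 at V_res during tau_ref)
        in_ref = st.refr > 0
        np.copyto(st.V, np.broadcast_to(self.V_res, st.V.shape),
                  where=in_ref)
        st.refr -= in_ref

        # threshold, reset, refractoriness
        spk = st.V >= self.V_th
        any_spk = spk.any()
        if any_spk:
            np.copyto(st.V, np.broadcast_to(self.V_res, st.V.shape),
                      where=spk)
            np.copyto(st.refr, np.broadcast_to(self.n_ref, st.refr.shape),
                      where=spk)
        spk_E = spk[:NE]
        spk_I = spk[NE:]

        # spike-triggered jumps (effective next step)
        if any_spk:
            if spk_E.any():
                if stp.enabled:
                    u_plus = st.u + stp.U * (1.0 - st.u)
                    drive = (st.u if stp.pre_jump_u else u_plus) * st.x
                    st.y_NMDA[spk_E] += drive[spk_E]
                    st.x[spk_E] -= drive[spk_E]
                    st.u[spk_E] = u_plus[spk_E]
                else:
                    st.y_NMDA[spk_E] += 1.0
            if spk_I.any():
                st.s_GABA[spk_I] += 1.0

        # background Poisson arrivals (effective next step)
        if counts is not None:
            st.s_AMPA_n += counts

        st.t += self.dt
        return spk_E, spk_I


def total_current(state: NetworkState, cfg: NetworkConfig,
                  profile: HeterogeneousProfile, I_e=None):
    """Instantaneous synaptic + external currents (nA) onto (E, I) neurons.

    Diagnostic view of the same current expressions used inside the
    integrator (reversal-potential driving forces, Mg2+ block on NMDA,
    per-contact conductance scaling).
    """
    if state.V.shape[0] != cfg.connectivity.N_E + cfg.connectivity.N_I:
        raise ValueError("total_current: state shape does not match config")
    kern = _Kernel(cfg, profile, dtype=np.float64)
    NE = kern.NE
    V = np.asarray(state.V, dtype=float)
    sN = np.asarray(state.s_NMDA, dtype=float)
    sG = np.asarray(state.s_GABA, dtype=float)
    sA = np.asarray(state.s_AMPA_n, dtype=float)
    rec = kern.WT @ sN
    sum_N = sN.sum(axis=0)
    sum_G = sG.sum(axis=0)
    block = mg_block(V, kern.cfg.synapse.Mg)
    nmda = np.empty_like(V)
    nmda[:NE] = kern.g_EE * rec
    nmda[NE:] = kern.g_EI * sum_N[None, :]
    g_exc = kern.g_AMPA * sA + nmda / block
    I = (kern.V_Erev - V) * g_exc \
        + (kern.V_Irev - V) * (kern.c_GABA * sum_G[None, :])
    if I_e is not None:
        I[:NE] += I_e
    return I[:NE], I[NE:]


def rk2_step(state: NetworkState, cfg: NetworkConfig,
             profile: HeterogeneousProfile, I_e=None,
             rng: np.random.Generator | None = None, dtype=np.float64):
    """One full network step: Heun update, threshold/reset, event jumps.

    If ``rng`` is given, background Poisson arrivals are drawn from it;
    otherwise the background is silent.  Returns (E spikes, I spikes) as
    boolean arrays.  Mutates ``state`` in place.
    """
    kern = _Kernel(cfg, profile, dtype=dtype)
    counts = None
    if rng is not None and cfg.synapse.poisson_rate > 0:
        counts = background_poisson(cfg.synapse.poisson_rate, cfg.sim.dt,
                                    rng, state.V.shape)
    spk_E, spk_I = kern.step(state, counts, I_e)
    if not np.isfinite(state.V).all():
        bad = np.argwhere(~np.isfinite(state.V))[0]
        raise NumericalError(
            f"non-finite membrane potential at t={state.t:.3f} ms "
            f"(neuron {bad[0]}, trial {bad[1]})")
    return spk_E, spk_I


# ---------------------------------------------------------------------------
# batched simulation driver
# ---------------------------------------------------------------------------

_CHUNK_STEPS = 512


def _chunk_counts(rng: np.random.Generator, lam: float, n_steps: int,
                  n_neurons: int) -> np.ndarray:
    """(n_steps, n_neurons) uint8 Poisson counts for one trial's chunk.

    Exact sparse construction of the independent Poisson field: the total
    number of arrivals in the chunk is Poisson(lam * cells) and each arrival
    lands in a uniformly random (step, neuron) cell, which makes the
    per-cell counts i.i.d. Poisson(lam).  Far cheaper than drawing one
    variate per cell when lam << 1.
    """
    cells = n_steps * n_neurons
    n_ev = rng.poisson(lam * cells)
    pos = rng.integers(0, cells, size=n_ev)
    counts = np.bincount(pos, minlength=cells).astype(np.uint8)
    return counts.reshape(n_steps, n_neurons)


def simulate_batch(cfg: NetworkConfig, profile: HeterogeneousProfile,
                   trial_seeds,
                   cue_profiles: np.ndarray | None = None,
                   extra_current: np.ndarray | None = None,
                   progress: Callable[[float], None] | None = None,
                   dtype=np.float32, engine: str = "auto") -> SimulationResult:
    """Integrate a batch of trials from t=0 to t_end.

    Parameters
    ----------
    trial_seeds : (B,) ints seeding the per-trial background-noise streams.
    cue_profiles : (N_E, B) cue currents (nA) applied to E neurons during
        [t_cue_on, t_cue_off); None for no cue.
    extra_current : (N_E,) or (N_E, B) constant current applied to E neurons
        at all times (used by tests and calibration probes).
    progress : optional callback receiving the current time (ms) at chunk
        boundaries.
    engine : "auto" (fused numba loops when available), "numba", or "numpy"
        (the reference kernel).  Both engines implement the identical update
        rules; "numpy" supports any dtype, the fused path is float32.
    """
    from . import _fast
    if engine == "auto":
        use_fast = _fast.HAVE_NUMBA and dtype == np.float32
    elif engine == "numba":
        if not _fast.HAVE_NUMBA:
            raise RuntimeError("numba engine requested but numba is missing")
        if dtype != np.float32:
            raise ValueError("numba engine is float32-only")
        use_fast = True
    elif engine == "numpy":
        use_fast = False
    else:
        raise ValueError(f"unknown engine {engine!r}")
    kern = _Kernel(cfg, profile, dtype=dtype)
    sim, prot, syn = cfg.sim, cfg.protocol, cfg.synapse
    dt = sim.dt
    trial_seeds = np.asarray(trial_seeds)
    B = trial_seeds.size
    NE, NI = kern.NE, kern.NI
    n_steps = int(round(prot.t_end / dt))
    stride = max(1, int(round(sim.sample_interval / dt)))
    on_step = int(round(prot.t_cue_on / dt))
    off_step = int(round(prot.t_cue_off / dt))

    st = make_state(cfg, B, dtype=dtype)
    noise_rngs = [np.random.default_rng([int(s), 0]) for s in trial_seeds]
    lam = syn.poisson_rate * dt

    # external current per phase, precombined once
    if extra_current is not None:
        extra_current = np.asarray(extra_current, dtype=dtype)
        if extra_current.ndim == 1:
            extra_current = np.broadcast_to(
                extra_current[:, None], (NE, B)).copy()
    I_out = extra_current
    if cue_profiles is not None:
        cue_profiles = np.asarray(cue_profiles, dtype=dtype)
        I_in = cue_profiles if I_out is None else cue_profiles + I_out
    else:
        I_in = I_out

    record = sim.record_V or sim.record_stp
    sample_steps = np.arange(stride, n_steps + 1, stride)
    n_samp = sample_steps.size
    V_samp = np.empty((NE, n_samp, B), np.float32) if sim.record_V else None
    u_samp = np.empty((NE, n_samp, B), np.float32) if sim.record_stp else None
    x_samp = np.empty((NE, n_samp, B), np.float32) if sim.record_stp else None

    sp_t, sp_n, sp_b = [], [], []
    spI_t, spI_n, spI_b = [], [], []
    samp_idx = 0
    rec_I = sim.record_I_spikes

    if use_fast:
        N = NE + NI
        f32 = np.float32
        fb = dict(
            G_in=np.empty((NE, 2 * B), f32), G_out=np.empty((NE, 2 * B), f32),
            k1s=np.empty((NE, B), f32), sum_N1=np.empty(B, f32),
            sum_N2=np.empty(B, f32), dV1=np.empty((N, B), f32),
            Vp=np.empty((N, B), f32), exp1=np.empty((N, B), f32),
            exp2=np.empty((N, B), f32),
            spkE_n=np.empty(NE * B, np.int32), spkE_b=np.empty(NE * B, np.int32),
            spkI_n=np.empty(NI * B, np.int32), spkI_b=np.empty(NI * B, np.int32),
        )
        zero_counts = np.zeros((N, B), np.uint8)
        dummy_ie = np.zeros((1, 1), f32)
        stp = cfg.stp
        c = dict(
            mg_c=f32(kern.mg_c), g_EE=f32(kern.g_EE), g_EI=f32(kern.g_EI),
            g_AE=f32(syn.g_AMPA_E * 1e-3), g_AI=f32(syn.g_AMPA_I * 1e-3),
            c_gE=f32(kern.c_GABA[0, 0]), c_gI=f32(kern.c_GABA[-1, 0]),
            g_LE=f32(cfg.neuron_E.g_L), g_LI=f32(cfg.neuron_I.g_L),
            invCE=f32(1.0 / cfg.neuron_E.C_m), invCI=f32(1.0 / cfg.neuron_I.C_m),
            V_LE=f32(cfg.neuron_E.V_L), V_LI=f32(cfg.neuron_I.V_L),
            V_Erev=f32(syn.V_E), V_Irev=f32(syn.V_I),
            alpha=f32(syn.alpha_S), inv_tauS=f32(1.0 / syn.tau_NMDA),
            f_y=f32(kern.f_y), f_GABA=f32(kern.f_GABA),
            f_u=f32(kern.f_u), f_x=f32(kern.f_x), U=f32(stp.U),
            V_thE=f32(cfg.neuron_E.V_th), V_thI=f32(cfg.neuron_I.V_th),
            V_resE=f32(cfg.neuron_E.V_res), V_resI=f32(cfg.neuron_I.V_res),
            dt32=f32(dt), f_AMPA=f32(kern.f_AMPA),
            n_refE=np.int16(kern.n_ref[0, 0]), n_refI=np.int16(kern.n_ref[-1, 0]),
        )

        def step_fn(counts_k, I_e):
            has_ie = I_e is not None
            ie = I_e if has_ie else dummy_ie
            _fast._stage_a(st.s_NMDA, st.y_NMDA, fb["G_in"], fb["k1s"],
                           fb["sum_N1"], fb["sum_N2"],
                           c["alpha"], c["inv_tauS"], c["dt32"])
            np.matmul(kern.WT, fb["G_in"], out=fb["G_out"])
            np.multiply(st.V, f32(-0.062), out=fb["exp1"])
            np.exp(fb["exp1"], out=fb["exp1"])
            sum_G1 = st.s_GABA.sum(axis=0)
            _fast._stage_b(st.V, fb["exp1"], st.s_AMPA_n, fb["G_out"][:, :B],
                           fb["sum_N1"], sum_G1, ie, has_ie,
                           fb["dV1"], fb["Vp"], NE,
                           c["mg_c"], c["g_EE"], c["g_EI"], c["g_AE"],
                           c["g_AI"], c["c_gE"], c["c_gI"], c["g_LE"],
                           c["g_LI"], c["invCE"], c["invCI"], c["V_LE"],
                           c["V_LI"], c["V_Erev"], c["V_Irev"],
                           c["f_AMPA"], c["dt32"])
            np.multiply(fb["Vp"], f32(-0.062), out=fb["exp2"])
            np.exp(fb["exp2"], out=fb["exp2"])
            nE, nI_ = _fast._stage_c(
                st.V, fb["Vp"], fb["exp2"], st.s_AMPA_n, st.s_NMDA,
                st.y_NMDA, st.s_GABA, st.u, st.x, st.refr,
                fb["G_out"][:, B:], fb["sum_N2"], sum_G1 * c["f_GABA"],
                ie, has_ie, fb["dV1"], fb["k1s"], fb["G_in"],
                counts_k if counts_k is not None else zero_counts,
                fb["spkE_n"], fb["spkE_b"], fb["spkI_n"], fb["spkI_b"], NE,
                c["mg_c"], c["g_EE"], c["g_EI"], c["g_AE"], c["g_AI"],
                c["c_gE"], c["c_gI"], c["g_LE"], c["g_LI"], c["invCE"],
                c["invCI"], c["V_LE"], c["V_LI"], c["V_Erev"], c["V_Irev"],
                c["alpha"], c["inv_tauS"], c["f_y"], c["f_GABA"],
                c["f_u"], c["f_x"], c["U"], stp.enabled, stp.pre_jump_u,
                c["V_thE"], c["V_thI"], c["V_resE"], c["V_resI"],
                c["n_refE"], c["n_refI"], c["dt32"])
            st.t += dt
            return (fb["spkE_n"][:nE].copy(), fb["spkE_b"][:nE].copy(),
                    fb["spkI_n"][:nI_].copy(), fb["spkI_b"][:nI_].copy())
    else:
        def step_fn(counts_k, I_e):
            spk_E, spk_I = kern.step(st, counts_k, I_e)
            n_idx, b_idx = np.nonzero(spk_E)
            if rec_I:
                nI_idx, bI_idx = np.nonzero(spk_I)
            else:
                nI_idx = bI_idx = np.empty(0, np.int64)
            return n_idx, b_idx, nI_idx, bI_idx

    for start in range(0, n_steps, _CHUNK_STEPS):
        stop = min(start + _CHUNK_STEPS, n_steps)
        S = stop - start
        counts = None
        if lam > 0:
            counts = np.empty((S, NE + NI, B), np.uint8)
            for b, rng in enumerate(noise_rngs):
                counts[:, :, b] = _chunk_counts(rng, lam, S, NE + NI)
        for k in range(start, stop):
            I_e = I_in if on_step <= k < off_step else I_out
            n_idx, b_idx, nI_idx, bI_idx = step_fn(
                None if counts is None else counts[k - start], I_e)
            if n_idx.size:
                sp_t.append(np.full(n_idx.size, (k + 1) * dt))
                sp_n.append(n_idx)
                sp_b.append(b_idx)
            if rec_I and nI_idx.size:
                spI_t.append(np.full(nI_idx.size, (k + 1) * dt))
                spI_n.append(nI_idx)
                spI_b.append(bI_idx)
            if record and samp_idx < n_samp and k + 1 == sample_steps[samp_idx]:
                if V_samp is not None:
                    V_samp[:, samp_idx, :] = st.V[:NE]
                if u_samp is not None:
                    u_samp[:, samp_idx, :] = st.u
                    x_samp[:, samp_idx, :] = st.x
                samp_idx += 1
        if not np.isfinite(st.V).all():
            bad = np.argwhere(~np.isfinite(st.V))[0]
            raise NumericalError(
                f"non-finite state at t={st.t:.2f} ms "
                f"(neuron {bad[0]}, trial {bad[1]})")
        if progress is not None:
            progress(st.t)

    def _cat(parts, dtype_=float):
        return (np.concatenate(parts).astype(dtype_) if parts
                else np.empty(0, dtype=dtype_))

    return SimulationResult(
        n_trials=B, t_end=prot.t_end, dt=dt,
        spike_t=_cat(sp_t), spike_neuron=_cat(sp_n, np.int32),
        spike_trial=_cat(sp_b, np.int32),
        sample_times=sample_steps * dt if record else None,
        V_samples=V_samp, u_samples=u_samp, x_samples=x_samp,
        spike_t_I=_cat(spI_t) if rec_I else None,
        spike_neuron_I=_cat(spI_n, np.int32) if rec_I else None,
        spike_trial_I=_cat(spI_b, np.int32) if rec_I else None,
    )
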