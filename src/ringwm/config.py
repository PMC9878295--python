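"""Structured configuration for the ring working-memory network.

All user-facing parameters live here, in "natural" units (ms, mV, nA, nS,
degrees for angles).  Internal simulation code works in radians; degree ->
radian conversion happens once, at this boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant.

    Collects *all* violations so a bad config file is reported in one shot.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire single-cell parameters."""

    C_m: float = 0.5        # membrane capacitance, nF
    g_L: float = 0.025      # leak conductance, uS
    V_L: float = -70.0      # resting potential, mV
    V_th: float = -50.0     # spike threshold, mV
    V_res: float = -60.0    # reset potential, mV
    tau_ref: float = 2.0    # absolute refractory period, ms

    def check(self, label, out):
        if not self.V_res < self.V_th:
            out.append(f"{label}: V_res must be < V_th")
        for name in ("C_m", "g_L", "tau_ref"):
            if getattr(self, name) <= 0:
                out.append(f"{label}: {name} must be > 0")


# Pyramidal cells have a 20 ms membrane time constant, interneurons 10 ms.
E_NEURON_DEFAULTS = dict(C_m=0.5, g_L=0.025, tau_ref=2.0)
I_NEURON_DEFAULTS = dict(C_m=0.2, g_L=0.020, tau_ref=1.0)


@dataclass
class SynapseParams:
    """Receptor kinetics, reversal potentials, and background drive.

    Recurrent excitation is NMDA-only (slow, saturating, Mg2+-blocked);
    recurrent inhibition is GABA_A; background noise arrives through AMPA
    receptors driven by independent 1 kHz Poisson trains.
    """

    V_E: float = 0.0            # excitatory reversal, mV
    V_I: float = -70.0          # inhibitory reversal, mV
    Mg: float = 1.0             # [Mg2+], mM
    g_AMPA_E: float = 2.48      # background AMPA conductance onto E cells, nS
    g_AMPA_I: float = 1.9       # background AMPA conductance onto I cells, nS
    tau_AMPA: float = 2.0       # AMPA gating decay, ms
    tau_GABA: float = 10.0      # GABA gating decay, ms
    tau_NMDA: float = 100.0     # NMDA gating decay tau_S, ms
    alpha_S: float = 1.0        # NMDA saturation rate, 1/ms
    tau_y: float = 2.0          # NMDA rise variable decay, ms
    poisson_rate: float = 1.0   # background Poisson rate, kHz (events/ms)

    def check(self, out):
        for name in ("tau_AMPA", "tau_GABA", "tau_NMDA", "tau_y"):
            if getattr(self, name) <= 0:
                out.append(f"synapse: {name} must be > 0")
        if self.Mg < 0:
            out.append("synapse: Mg must be >= 0")
        if self.poisson_rate < 0:
            out.append("synapse: poisson_rate must be >= 0")


@dataclass
class STPParams:
    """Tsodyks-Markram short-term plasticity on E->E NMDA transmission.

    ``u`` (utilization) facilitates toward 1 on spikes and relaxes to U with
    tau_u; ``x`` (resources) depletes on spikes and recovers to 1 with tau_x.
    The effective per-spike drive is u*x.  With ``enabled=False`` the drive
    is the constant 1 (the plasticity-removed control).
    """

    U: float = 0.8
    tau_u: float = 1650.0   # facilitation recovery, ms
    tau_x: float = 250.0    # depression recovery, ms
    enabled: bool = True
    pre_jump_u: bool = False  # use pre-facilitation u in the spike drive

    def check(self, out):
        if not (0.0 < self.U <= 1.0):
            out.append("stp: U must be in (0, 1]")
        if self.tau_u <= 0 or self.tau_x <= 0:
            out.append("stp: tau_u and tau_x must be > 0")


@dataclass
class ConnectivityParams:
    """Ring-network sizes, heterogeneity profile, and coupling scales.

    ``b`` controls heterogeneity strength (b -> inf is the homogeneous
    ring); ``n_peaks`` equally spaced preference peaks carry stronger,
    narrower recurrent footprints.  Conductance scales are *totals* in nS:
    the per-contact conductance is G / N_presynaptic.
    """

    N_E: int = 512
    N_I: int = 128
    b: float = 1.2                # heterogeneity control, dimensionless
    J_bar: float = 4.9            # mean footprint amplitude
    sigma_bar_deg: float = 4.0    # reference footprint width, degrees
    S_N: float = 10.0             # heterogeneity peak width, index units
    n_peaks: int = 4
    G_EE_NMDA: float = 1350.0     # total E->E NMDA conductance, nS
    G_EI_NMDA: float = 735.0      # total E->I NMDA conductance, nS
    G_IE_GABA: float = 1440.0     # total I->E GABA conductance, nS
    G_II_GABA: float = 768.0      # total I->I GABA conductance, nS
    # which side of an E->E contact owns the heterogeneous footprint:
    # "pre" = each neuron's OUTGOING weight profile is (J_i+, sigma_i) and
    # sums to 1 (bumps drift toward the connectivity peaks); "post" = each
    # neuron's incoming profile is normalized instead.
    footprint_side: str = "pre"

    def check(self, out):
        if self.N_E < 1 or self.N_I < 1:
            out.append("connectivity: N_E and N_I must be >= 1")
        if self.b <= 0:
            out.append("connectivity: b must be > 0")
        if not (0.0 < self.sigma_bar_deg < 180.0):
            out.append("connectivity: sigma_bar_deg must be in (0, 180)")
        if self.n_peaks < 1:
            out.append("connectivity: n_peaks must be >= 1")
        if self.footprint_side not in ("pre", "post"):
            out.append("connectivity: footprint_side must be 'pre' or 'post'")
        for name in ("G_EE_NMDA", "G_EI_NMDA", "G_IE_GABA", "G_II_GABA"):
            if getattr(self, name) < 0:
                out.append(f"connectivity: {name} must be >= 0")

    @property
    def sigma_bar(self) -> float:
        """Reference footprint width in radians."""
        return np.deg2rad(self.sigma_bar_deg)


@dataclass
class ProtocolParams:
    """Trial structure: cue timing, stimulus statistics, batch size."""

    t_cue_on: float = 50.0      # ms
    t_cue_off: float = 150.0    # ms
    t_end: float = 1150.0       # ms (cue period + delay)
    load: int = 1               # number of simultaneous stimuli (1 or 2)
    I0: float = 0.05            # cue strength, nA * rad (calibrated)
    sigma_s_deg: float = 2.0    # cue profile width, degrees
    min_sep_deg: float = 25.0   # minimum circular separation of stimuli
    n_trials: int = 4000
    base_seed: int = 12345

    def check(self, out):
        if not (0 <= self.t_cue_on < self.t_cue_off <= self.t_end):
            out.append("protocol: need 0 <= t_cue_on < t_cue_off <= t_end")
        if self.sigma_s_deg <= 0:
            out.append("protocol: sigma_s_deg must be > 0")
        if self.min_sep_deg < 0:
            out.append("protocol: min_sep_deg must be >= 0")
        if self.load < 1:
            out.append("protocol: load must be >= 1")
        if self.load * self.min_sep_deg >= 360.0:
            out.append("protocol: load * min_sep_deg must be < 360")
        if self.n_trials < 1:
            out.append("protocol: n_trials must be >= 1")

    @property
    def sigma_s(self) -> float:
        return np.deg2rad(self.sigma_s_deg)

    @property
    def delay(self) -> float:
        return self.t_end - self.t_cue_off


@dataclass
class DecodeParams:
    """Rate estimation and bump segmentation settings."""

    rate_window: float = 50.0    # causal boxcar length, ms
    smooth_sigma: float = 5.0    # circular spatial smoothing, neuron indices
    baseline: float = 2.0        # bump membership threshold, Hz
    gap_tol: int = 3             # sub-threshold gap merged inside an arc, neurons
    min_arc_width: int = 3       # arcs narrower than this are noise, neurons
    merge_tol_deg: float = 30.0  # stimulus adopts another's arc within this
    claim_tol_deg: float = 60.0  # max arc-to-stimulus distance for a claim
    fade_window: float = 100.0   # final window used for fade detection, ms

    def check(self, out):
        if self.rate_window <= 0:
            out.append("decode: rate_window must be > 0")
        if self.baseline < 0:
            out.append("decode: baseline must be >= 0")
        if self.gap_tol < 0 or self.min_arc_width < 1:
            out.append("decode: gap_tol must be >= 0 and min_arc_width >= 1")


@dataclass
class SimParams:
    """Numerical integration and recording settings."""

    dt: float = 0.02             # integration step, ms
    sample_interval: float = 1.0  # state-sampling interval, ms
    record_V: bool = False       # sample E membrane potentials
    record_stp: bool = False     # sample u, x
    record_I_spikes: bool = False

    def check(self, out):
        if self.dt <= 0:
            out.append("sim: dt must be > 0")
        if self.sample_interval < self.dt:
            out.append("sim: sample_interval must be >= dt")


@dataclass
class NetworkConfig:
    """Complete model configuration (all sub-blocks with paper defaults)."""

    neuron_E: NeuronParams = field(
        default_factory=lambda: NeuronParams(**E_NEURON_DEFAULTS))
    neuron_I: NeuronParams = field(
        default_factory=lambda: NeuronParams(**I_NEURON_DEFAULTS))
    synapse: SynapseParams = field(default_factory=SynapseParams)
    stp: STPParams = field(default_factory=STPParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    decode: DecodeParams = field(default_factory=DecodeParams)
    sim: SimParams = field(default_factory=SimParams)

    def validate(self) -> "NetworkConfig":
        out: list[str] = []
        self.neuron_E.check("neuron_E", out)
        self.neuron_I.check("neuron_I", out)
        self.synapse.check(out)
        self.stp.check(out)
        self.connectivity.check(out)
        self.protocol.check(out)
        self.decode.check(out)
        self.sim.check(out)
        if out:
            raise ConfigError(out)
        return self

    # ---- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "NetworkConfig":
        data = dict(data or {})
        kwargs = {}
        violations = []
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for name, f in fields.items():
            block = data.pop(name, None)
            sub_cls = _BLOCK_TYPES[name]
            if block is None:
                kwargs[name] = None
            else:
                known = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(block) - known
                if unknown:
                    violations.append(
                        f"{name}: unknown keys {sorted(unknown)}")
                kwargs[name] = sub_cls(
                    **{k: v for k, v in block.items() if k in known})
        if data:
            violations.append(f"unknown top-level keys {sorted(data)}")
        if violations:
            raise ConfigError(violations)
        # fill defaults for missing blocks
        if kwargs.get("neuron_E") is None:
            kwargs["neuron_E"] = NeuronParams(**E_NEURON_DEFAULTS)
        if kwargs.get("neuron_I") is None:
            kwargs["neuron_I"] = NeuronParams(**I_NEURON_DEFAULTS)
        for name in ("synapse", "stp", "connectivity", "protocol",
                     "decode", "sim"):
            if kwargs.get(name) is None:
                kwargs[name] = _BLOCK_TYPES[name]()
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


_BLOCK_TYPES = {
    "neuron_E": NeuronParams,
    "neuron_I": NeuronParams,
    "synapse": SynapseParams,
    "stp": STPParams,
    "connectivity": ConnectivityParams,
    "protocol": ProtocolParams,
    "decode": DecodeParams,
    "sim": SimParams,
}


def load_config(path) -> NetworkConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the full default configuration.  Unknown keys and
    out-of-range values are reported together in a single :class:`ConfigError`.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return NetworkConfig.from_dict(data or {})


def save_config(cfg: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
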