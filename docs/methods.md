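# Model and methods

## The network

`ringwm` simulates a conductance-based spiking network of 512 excitatory
(E) and 128 inhibitory (I) leaky integrate-and-fire neurons.  Each E neuron
is assigned a preferred color theta_i = 2*pi*i/N_E on the color wheel.
Membrane dynamics follow

    C_m dV/dt = -g_L (V - V_L) + I_syn,

with a spike emitted at V >= V_th = -50 mV, reset to V_res = -60 mV, and an
absolute refractory period (2 ms for E cells, 1 ms for I cells) during
which V is clamped at V_res.  E cells have C_m = 0.5 nF, g_L = 0.025 uS
(tau_m = 20 ms); I cells 0.2 nF, 0.020 uS (tau_m = 10 ms); V_L = -70 mV.

Synaptic currents use the depolarizing-positive convention
I = -(V - V_rev) g s.  Recurrent excitation is NMDA-only, with the
voltage-dependent magnesium block

    I_NMDA = -(V - V_E) * g * s / (1 + [Mg] exp(-0.062 V)/3.57),

[Mg] = 1 mM.  NMDA gating is second order: a fast rise variable y (tau_y =
2 ms) jumps at presynaptic spikes and drives the saturating gating variable
ds/dt = -s/tau_S + alpha_S y (1 - s) with tau_S = 100 ms, alpha_S = 1/ms.
Recurrent inhibition is GABA_A (tau = 10 ms, V_I = -70 mV); background
drive arrives through AMPA receptors (tau = 2 ms) fed by independent 1 kHz
Poisson trains per neuron (2.48 nS onto E cells, 1.9 nS onto I cells).
Fast recurrent AMPA excitation is omitted; the delay-period activity is
carried by NMDA.

### Short-term plasticity

E->E transmission carries Tsodyks-Markram short-term plasticity.  Each
presynaptic E neuron tracks utilization u (facilitates by U(1-u) per spike,
relaxes to U with tau_u = 1,650 ms) and resources x (depletes by the
transmitted drive per spike, recovers to 1 with tau_x = 250 ms).  The
per-spike NMDA drive is u*x evaluated with the post-facilitation u
(u+ * x-, the convention of the standard synaptic-theory literature; the
pre-jump alternative is available behind `STPParams.pre_jump_u`).  With
U = 0.8 the synapse is depression-dominated: a bump firing at 30-60 Hz
transmits at only ~10-25 % efficacy.  The "plasticity removed" control
replaces the drive u*x by the constant 1 and leaves u, x untouched.

### Heterogeneous connectivity

The E->E footprint is a Gaussian of the circular preference difference on
a uniform baseline,

    W(dtheta; i) = J_i^- + (J_i^+ - J_i^-) exp(-dtheta^2 / 2 sigma_i^2).

Heterogeneity enters through a periodic profile y_i with `n_peaks` equally
spaced maxima (4 by default, at 45/135/225/315 deg; 3 in the three-peak
variant): y_i = 1 - (1/b)[1 - exp(-d_i^2/S_N^2)/sqrt(2 pi)], where d_i is
the index distance to the nearest peak, S_N = 10 for N = 512, and b = 1.2
(b -> infinity recovers the homogeneous ring).  Amplitudes are
J_i^+ = J_bar * N * y_i / sum_j y_j (mean exactly J_bar = 4.9; the
exponent sign in y and the mean-versus-maximum reading of J_bar follow the
printed formulas, which are the self-consistent choice).  The shared
baseline J^- and the per-neuron widths sigma_i are fixed by requiring each
footprint to average to 1 over the circle:

    J^- = (1 - J_bar c(sigma_bar)) / (1 - c(sigma_bar)),
    c(sigma) = (sigma/sqrt(2 pi)) erf(pi / (sqrt(2) sigma)),

with sigma_bar = 4 deg, giving J^- = 0.8883, and sigma_i solving
c(sigma_i) = (1 - J^-)/(J_i^+ - J^-) by bracketed root finding (residual
< 1e-10).  Peak neurons therefore have large, narrow footprints
(J^+ ~ 11.5, sigma ~ 1.5 deg), trough neurons flat, broad ones
(J^+ ~ 3.8, sigma ~ 5.4 deg).

**Which side of a contact owns the footprint.**  The formula is symmetric
on paper but not in the physics.  We parameterize the footprint by the
*presynaptic* neuron: the conductance of the contact j -> i is
G_EE * W(dtheta_{j,i}; j) / N_E, i.e. each neuron's outgoing weight
profile is its own (J^+, sigma) Gaussian and sums to one.  A frozen-bump
mean-field calculation (and direct simulation) shows why this matters:
with *postsynaptic* (input-normalized) footprints, a peak neuron's narrow
receptive range starves it of input from any bump more than a few degrees
away, so bumps drift *away* from the connectivity peaks toward the
troughs, inverting the model's central behavior.  With outgoing
footprints the activated neurons near a peak project strongly and locally
toward it, and bumps drift toward the peaks at every bump width — the
mechanism the model is built around.  The matrix constructed by the
connectivity module satisfies the per-column normalization either way;
`ConnectivityParams.footprint_side` ("pre" default, "post") selects which
index the dynamics contracts.  Couplings from and onto I neurons are
uniform with per-contact scaling G / N_presynaptic.

### Calibrated conductance scales

The four coupling totals (G_EE_NMDA, G_EI_NMDA, G_IE_GABA, G_II_GABA) and
the cue strength I0 are not constrained by first principles here; they are
set by the shipped calibration procedure (`protocol.calibrate_defaults`):
the spontaneous state must stay below 5 Hz without a cue, and a load-1 cue
must ignite an activity bump that survives the full delay.  Within the
stable region the network's qualitative regime varies strongly (see
"Operating regime" below), and the shipped defaults were chosen once, at
the point that best reproduces the clustered-report phenomenology.

## Simulation protocol

A trial presents `load` (1 or 2) cue currents
I_e(theta_i) = sum_a I0/(sqrt(2 pi) sigma_s) exp(-d(theta_i,theta_a)^2 /
2 sigma_s^2) (circular distance, sigma_s = 2 deg, I0 calibrated) to the E
population from 50 to 150 ms, then lets the network run to t_end (up to
3,150 ms; the reduced desk-scale profile uses 1,150 ms, i.e. a 1,000 ms
delay).  Stimuli are uniform on the color wheel, rejection-sampled so that
pairwise separations exceed 25 deg.  Integration is fixed-step Heun (RK2)
at dt = 0.02 ms: membrane and the nonlinear NMDA gating ODE go through the
two-stage update (the recurrent sum is re-evaluated at both stages);
purely linear decays use exact exponential factors; thresholds are checked
once per step, and spike-triggered jumps (STP, gating, reset) apply at the
end of the step.  Background Poisson arrivals are generated per trial from
counter-seeded streams ([trial_seed, 0]), with guess reports and stimulus
draws on separate streams ([trial_seed, 1], [trial_seed, 2]), so every
trial is bit-reproducible alone or inside any batch.

The batched integrator keeps state as (neuron, trial) float32 arrays; the
E->E recurrent sums of both Heun stages are one BLAS sgemm per step and
the remaining elementwise work is fused with numba (with a pure-NumPy
reference kernel, equivalence-tested, as fallback).  Float32 state is a
deliberate numerical choice: per-step increments are ~1e-4 relative, four
orders of magnitude above float32 resolution, and the single-neuron
closed-form tests (spike-interval formula to 0.1 %, dt-halving
convergence below 0.01 mV RMS) run identically in float64.

## Decoding and reports

Firing rates are causal 50 ms boxcar counts per neuron on a 1 ms grid,
smoothed circularly across neurons (Gaussian, sigma = 5 neurons).  At each
time the supra-baseline (2 Hz) neurons form contiguous arcs (gaps <= 3
neurons bridged; arcs < 3 neurons wide are discarded as noise blips); each
arc is claimed by the nearest stimulus within 60 deg, a stimulus left
empty adopts a neighboring arc within 30 deg (merged bumps report
together), and the remembered color is the population-vector angle
arg sum_j r_j exp(i theta_j) over the stimulus's subpopulation.  A
stimulus with no supra-baseline arc at any time during the final 100 ms
has faded and reports a uniform random guess.  The rate window, smoothing
width, and tolerances are configuration, not constants; the defaults were
chosen before the end-to-end experiments and are logged with every run.

## Analysis

Report errors are wrapped to [-180, 180) deg.  The error histogram
(default 10 deg bins, always logged with the SSE) is fit by least squares
with amp * exp(-(e-mu)^2/2 sigma^2), sigma capped at the 180 deg
half-support (an unbounded sigma just refits a constant).  Cluster
structure is quantified two ways: a Rayleigh test on the k-th circular
moment (k = number of connectivity peaks), and mode counting on a von
Mises KDE.  The KDE concentration defaults to kappa = min(50, max(6, n/8))
— resolution adapted to sample size — and a mode must clear both 0.2 of
the density maximum and 3.5 analytic null standard deviations
(sqrt((I0(2k)/I0(k)^2 - 1)/n) relative, the pointwise fluctuation of a
uniform-sample KDE).  The second guard is what keeps a 100-200-trial
uniform sample from showing spurious clusters; at a fixed kappa = 50 a
uniform sample of that size *always* shows several.

Membrane-potential statistics take each E neuron's mean and s.d. over the
final 1,000 ms of 1 ms samples; "inside the bump" means within twice the
supra-baseline half-width of the decoded center (capped so a wide plateau
still leaves an outside).  STP spatiotemporal maps record u, x on the 1 ms
grid; the flank-asymmetry index is the difference in mean depression
(U - u*x) between the two 45 deg flanks of the cue, positive when the
counterclockwise flank is more depressed.

## The drift-diffusion reference

The comparison model evolves a single trace d theta = beta G(theta) dt +
sigma dW with G = (1/2) d/dtheta of a 12-component von Mises mixture
(means 2*pi*j/12, weights from the fitted set, width parameter 2*pi/12
read as a circular s.d. with kappa = 1/s^2; reading it directly as kappa
is a config option).  Integration is Euler-Heun (Stratonovich); reports
follow the same guess-rate logic (swap rate 0 at load 1).  With the
fitted beta = 0.0917, sigma = 3.637e-4 and uniform initial angles the
terminal distribution clusters at the mixture modes while the *error*
distribution is bimodal with a dip at zero: the displacement field of a
finite-time flow to discrete attractors has its density maxima at the
extreme displacements, not at zero.  This is the qualitative mismatch
with behavioral error distributions that motivates the spiking model.

## Operating regime and known limitations

The free conductance scales select among qualitatively different regimes,
mapped during calibration:

* **Tight bumps** (strong E->I feedback): narrow (~40 deg) bumps that
  drift reliably *toward* the nearest connectivity peak but park a
  satellite distance (~10-20 deg) short of it within a 1 s delay; report
  errors are small (s.d. ~6-8 deg) and clustering is correspondingly
  partial.
* **Wide plateaus** (weaker feedback): activity spans ~160 deg and locks
  with its edges pinned on two connectivity peaks, putting the decoded
  center *on* a peak; clustering at 1 s is strong (70-80 % of reports
  within 15 deg of a peak) at the price of larger errors and a
  wander-dominated approach whose direction is set by the "moat"
  structure of the total-input-weight landscape rather than by the local
  drift the narrative describes.

The shipped defaults use the wide-plateau point (G_EE = 1350 nS,
G_EI = 735 nS, G_IE = 1440 nS, G_II = 768 nS, I0 = 0.05 nA rad), which
reproduces the headline phenomenology — clustered reports at the
connectivity-peak angles with a roughly Gaussian error distribution,
uniform reports in the homogeneous control, narrower errors without
plasticity — at a 1,000 ms delay and ~10^2 trials.  Known limitations,
measured honestly at this point:

* The plasticity-removed control saturates the NMDA gating (s ~ 0.95),
  which washes out the heterogeneity contrast; its reports stay near the
  stimuli instead of re-clustering within 1 s.  Clustering without STP
  needs the slower drift to act over multi-second delays.
* The flank-asymmetry orientation and the inside-bump V-fluctuation
  comparison are regime-dependent: in the wide-plateau regime the plateau
  expands toward the *farther* moat, reversing the asymmetry sign (the
  corresponding end-to-end tests fail at the shipped defaults and are
  expected to); in the tight regime the orientation is correct in
  ~95-100 % of trials but clustering is too weak.
* The generator's defaults emulate the study conditions (parameter values
  above, uniform stimuli, 1 kHz background); they do not emulate
  behavioral lapses, motor noise, or trial-to-trial parameter drift, so
  passing tests speak to the model's internal consistency, not to fits of
  human data.

A geometric consequence of the plateau mechanism is worth stating
explicitly: a ~160 deg plateau spans half the ring, so in the four-peak
network its edges pin on two *opposite* peaks and the decoded center
falls on the peak between them, whereas in the three-peak network
(120 deg cells) and in the saturated plasticity-removed network the same
edge-pinning leaves the center half a cell away, at the troughs.  Both
variants therefore still show n-fold clustered reports, displaced from
the connectivity peaks by half a cell.

Problem sizes: the shipped experiments default to 110-200 trials at a
1,000 ms delay, sized for the mode detector's power at the observed
peak-capture fraction (the full-scale profile, 4,000 trials at 3,000 ms,
is the same code path with different parameters).  All analysis defaults
(windows, bandwidths, thresholds) are recorded next to every output.
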