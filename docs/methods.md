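# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the design decisions taken where the underlying study left
the design open. Units throughout: mV, ms, nA, nS, µA/cm², mS/cm²,
µF/cm², µm, Ω·cm.

## Morphology and passive properties

The cell is a ball-and-stick layer-5 pyramidal neuron: a cylindrical soma
(20 µm length × 20 µm diameter), a 500-µm apical trunk divided into 100
segments of 5 µm (diameter 2 µm, untapered), two accessory apical
dendrites (150 × 1 µm, 10 segments each) attached at the distal end of the
trunk, and a single spine — 1 × 1 µm head on a 1 × 0.07 µm neck — attached
to the trunk compartment whose center lies 122.5 µm from the soma. The
GABA-A synapse contacts that same trunk ("shaft") compartment. Passive
parameters are standard cortical values: C_m = 1 µF/cm², R_a = 150 Ω·cm,
g_L = 0.033 mS/cm², E_L = −70 mV. The soma and accessory-dendrite
dimensions are package choices (the source model geometry is not fully
specified); all acceptance-level properties were required to be robust to
them, and the spatial-refinement test (200 × 2.5 µm trunk) bounds the
discretization sensitivity of the synapse-site AP peak at < 0.5 mV.

Compartment positions are measured at segment centers along the trunk
axis; the axial coupling between a compartment and its parent is the
series combination of the two half-compartment axial resistances.

## Mechanisms

Four voltage-gated conductances, all ohmic with Hodgkin–Huxley gating
(exact exponential gate updates m ← m∞ + (m − m∞)e^(−dt/τ) at the step's
voltage):

- **Na, 4 mS/cm², uniform, E_Na = +60 mV, m³h.** Classic squid-type rate
  functions referenced to a −65 mV rest, with all rates scaled 2.5×. The
  scaling narrows the somatic spike to ~1–1.5 ms and speeds recovery from
  inactivation; without it, spikes deposit so much charge that
  high-frequency trains ride on a depolarized envelope and the test spike
  after a train is strongly adapted — artifacts that would masquerade as
  (or mask) the A-type effects under study.
- **Delayed rectifier K_dr, 0.1 mS/cm² along the dendrite and spine,
  15 mS/cm² at the soma, E_K = −70 mV, n⁴.** n∞ half −50 mV (k = 6 mV);
  τ_n ≈ 0.8 ms when depolarized and ≈ 7 ms subthreshold, i.e. fast
  activation, moderately slow deactivation. The lingering conductance
  restores the membrane toward rest after each spike. Two deliberate
  choices here: (i) E_K is set equal to the chloride/leak reversal
  (−70 mV), so no potassium current can drive any compartment below the
  GABA-A reversal — the model's lower voltage bound is exactly −70 mV and
  the rectifier acts as a pure "return-to-rest" force with no
  afterhyperpolarization undershoot; (ii) the somatic density is much
  higher than the dendritic one. The dendritic density is a fixed property
  of the cell being modelled; the somatic density is not specified by it,
  and a dense perisomatic rectifier is both physiological and necessary —
  with only 0.1 mS/cm² everywhere, the membrane time constant (~30 ms)
  leaves the cell depolarized for tens of milliseconds after each spike,
  which inflates the IPSP driving force in train protocols and reverses
  the occlusion prediction.
- **A-type K_A, a·b, E_K = −70 mV.** Density zero at the soma and over the
  proximal trunk segment, rising linearly along the trunk: the ramp is
  anchored at segment centers (zero at 2.5 µm, the distal maximum
  `g_distal` at 497.5 µm, clipped to [0, g_distal]), which reproduces the
  published synapse-site values 17.0 mS/cm² (g_distal = 70) and
  2.4 mS/cm² (g_distal = 10) at 122.5 µm; a naive ramp g·x/L does not
  (17.15/2.45). Accessory apical dendrites and the spine head carry the
  distal and parent-shaft densities respectively; the spine neck is
  passive. Activation a: half −15 mV, k = 12 mV, τ 0.5–2.3 ms — fast
  enough to clip the rising bAP. Inactivation b: steep and low-voltage
  (half −57 mV, k = 3 mV), τ ≈ 6 ms when depolarized rising to ≈ 100 ms at
  rest. This places inactivation under the control of small sustained
  depolarizations: the inter-spike envelope of a 100-Hz train drives b
  from ~0.95 to ~0.55 (less at 50 Hz), and the 20-ms gap before a test
  pulse recovers only a small part — the substrate of the
  activity-dependent enhancement and its frequency dependence. 4-AP is
  modelled exclusively as a reduction of the distal maximum (70 → 10
  mS/cm²); no other parameter changes between "control" and "low"
  conditions.
- **Reporter Ca, 10⁻⁷ mS/cm² in the spine head and the shaft compartment,
  E_Ca = +120 mV, m².** Medium-threshold activation (half −30 mV,
  k = 9 mV, τ = 2 ms), no inactivation. At this density the channel
  carries ~10⁻⁶ µA/cm² — a pure voltage readout with no feedback on the
  membrane. Because the bAP at the synapse site peaks between roughly −35
  and −25 mV, i.e. on the rising foot of the activation curve, and because
  the 2-ms activation lag keeps the gate far from equilibrium during a
  ~1-ms spike, the peak Ca current is a convex (supralinear) function of
  the peak voltage across the density sweep — the central mechanism.

The GABA-A synapse is the difference-of-exponentials conductance
g(t) = g_max·N·(e^(−t/τ₂) − e^(−t/τ₁)) with τ₁ = 5 ms, τ₂ = 74 ms and N
chosen so the peak equals g_max = 2 nS (peak-normalization convention,
matching the weight semantics of the standard two-exponential synapse
mechanism). It is integrated as two exactly-decaying states with event
increments resolved to the nearest solver step (≤ 2.5 µs timing error at
the default dt).

## Numerics

Backward (implicit) Euler at dt = 0.005 ms. Each step advances all gates
by their exact exponential update at the step's starting voltage, then
solves the linear cable system (membrane conductances evaluated at the
updated gates, voltage fully implicit) by Hines-ordered elimination on the
tree — an exact O(n) solve, verified against dense linear algebra to
1e−10 mV on small instances. The compiled (numba) kernel evaluates gate
steady states and per-step decay factors by linear interpolation on a
0.01-mV voltage grid built from the same GateSpec functions as the
pure-Python reference stepper; kernel and reference agree to < 2×10⁻³ mV
over hundreds of active steps, and halving dt changes the somatic AP peak
by < 0.06 mV. Simulations are bit-reproducible for identical inputs.

Resting states are computed by a damped fixed-point iteration (gates at
steady state, linear solve for V) rather than by long settling runs; the
holding-current search is then a secant iteration on the steady-state
somatic voltage as a function of injected current, which stays entirely in
the subthreshold regime and lands within 10⁻⁶ mV of the −64 mV target
(criterion: 10⁻³ mV, verified by 500-ms simulation for every sweep
condition). The spike stimulus is calibrated by bisection (0.01 nA
resolution, bracket initialized at the experimental 1.5–2.5 nA) to the
smallest 0.5-ms somatic pulse evoking exactly one spike, where a spike is
an upward crossing of 0 mV at the soma. Protocol studies then step the
amplitude up (0.05-nA grid) until the pulse is reliable in every trial
variant used — with a preceding IPSP and, for train studies, for all five
train pulses and the delayed test pulse at every frequency — mirroring the
experimental use of a fixed suprathreshold pulse and the exclusion of
cells whose pulses failed or burst. Amplitude windows that produce
doublets are skipped.

## Quantification

The calcium response of a trial is the trapezoidal integral of the
reporter-current magnitude over the half-open window [t_test,
t_test + 100 ms). Inhibition fractions compare *evoked* responses with the
same pairing arithmetic as the fluorescence analysis: the control response
subtracts the standing (resting) reporter current (trials start from the
held steady state, so the first sample defines the pedestal); the
inhibited response subtracts the matched inhibition-alone trial, which
removes both the pedestal and the IPSP-induced dip in standing influx;
train responses subtract their train-alone baselines
(ΔCa = flux(train+test) − flux(train-alone), and analogously with IPSP).
The data for this arithmetic are exactly the seven interleaved trial types
of the experimental design. AP metrics use a fixed −64 mV baseline:
half-width is the full width at half amplitude above that baseline (linear
interpolation between samples), so widths are comparable across train
conditions; waveforms rising less than 10 mV above baseline are flagged as
absent spikes. "Approximately constant" for the GABAergic peak reduction
across the sweep is operationalized as: coefficient of variation < 0.5 and
range smaller than half the range of the control peak itself.
Supralinearity is all-positive second differences (consecutive-slope
differences on sorted x) of |peak I_Ca| versus peak V across the 7-point
density sweep.

## Synthetic imaging stage

The generator emulates the structure of the two-photon line-scan data the
experimental analysis assumes — not the optics. Per cell (one spine/shaft
pair, as in the experiments) and per trial type it produces `n_trials`
(default 10) two-channel traces at a 500-Hz line rate:

- **Ca proxy.** The model reporter current magnitude is integrated by a
  leaky integrator with a 50-ms decay (initialized at its resting level so
  baselines are flat) and scaled to concentration
  (4×10⁵ µM per µA·ms/cm², placing a single-bAP spine transient near 20%
  of indicator saturation — the low-affinity-indicator regime).
- **Indicator.** Single-site Hill binding, K_d = 2.3 µM, G₀ = 100,
  G_sat = 600 a.u.; a linear-indicator mode (the K_d → ∞ limit at matched
  initial slope) exists for validation. The red channel is constant at
  200 a.u.
- **Noise and artifacts.** Additive Gaussian noise (SD 10 a.u. per line
  sample) on both channels; Poisson shot noise is a config option. Light
  (uncaging) trials carry an exponential blue-light photoartifact
  (30 a.u., 2-ms decay) on the green channel from the uncaging time.
- **Population structure.** Per-cell response amplitudes vary lognormally
  (CV 0.2); per-trial seeds derive deterministically from a master seed by
  SeedSequence spawning (one child per cell, one generator per cell used
  across its conditions, so conditions are paired through the cell).

All indicator and noise defaults are configuration, not claims about any
particular dataset. The analysis chain is the experimental one: per-trial
ΔG/R against the pre-event baseline, re-expressed as a fraction of the
saturating-Ca G/R ratio (a calibration constant of the config),
photoartifact removal by subtracting the uncaging-alone average, 10-trial
averages, 100-ms integrals, paired inhibition fractions, exact Wilcoxon
statistics. With zero noise and a linear indicator the chain recovers the
concentration-space fraction to < 10⁻⁶; with Hill binding the recovered
fraction is biased low, one-signedly and increasingly with transient
amplitude (saturation compresses the larger control response more). Tests
pass on this synthetic stage therefore validate the *arithmetic* of the
analysis, including its robustness to saturation bias and noise — they say
nothing about optics, motion, bleaching, or indicator kinetics beyond
single-site equilibrium binding, which are deliberately out of scope.

The exact Wilcoxon matched-pairs signed-rank test drops zero differences,
assigns average ranks to ties, computes the full null distribution of the
positive-rank sum by convolution over doubled ranks (exact for any
practical n; equivalent to 2ⁿ enumeration, against which it is tested),
and doubles the smaller tail, capped at 1. At n = 10 the attainable
two-sided level below 0.05 is 0.04883, and the zero-effect population
study reproduces that rate across 1000 master seeds within binomial error.

## Problem sizes and runtimes

The default model has 123 compartments; trials span 190–270 ms of
simulated time (40-ms baseline, all events, ≥ 130 ms after the test
pulse) at dt = 0.005 ms. The density sweep uses the full 7-point grid with
per-condition recalibration; the train study runs the complete seven-type
trial set at two densities and two frequencies; the type-I-error study
uses 1000 seed replicates of a 10-cell population built on analytic
synthetic trials. These sizes keep the full test suite under a minute
after kernel compilation while exercising every study at its design scale.

## Known limitations

- The 50-vs-100 Hz separation of the enhancement is small (the ordering is
  robust, the margin is not large): with only two K_dr densities and one
  A-type inactivation time constant, the inter-spike envelope at 50 Hz is
  not dramatically milder than at 100 Hz.
- The occlusion of the train effect at low A-type density is partial, as
  it must be: the "low" condition retains 14% of the channels, and the
  fraction-versus-density curve is steepest exactly there.
- Channel kinetics are package constructions constrained by qualitative
  behavior (activation by depolarization, low-voltage inactivation with
  slow recovery, 4-AP as density scaling), not fits to voltage-clamp data.
- No NMDA/AMPA/GABA_B receptors, no intracellular Ca dynamics (the
  reporter-current integral is the calcium readout), no temperature
  scaling, no stochastic gating, single spine only, simplified geometry.
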