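# Methods

## Model

The simulator integrates the spatial Hodgkin–Huxley system on a
one-dimensional cable x ∈ [0, L] with sealed ends (∂V/∂x = 0 at both
boundaries, so arriving spikes terminate without reflection):

    C_m V_t = D C_m V_xx − I_ion(V, n, m, h) + I_drive(x, t),
    x_t = α_x(V)(1 − x) − β_x(V) x,   x ∈ {n, m, h},

with D = a/(2 R_i C_m) the voltage diffusion coefficient set by fiber
radius a, axial resistivity R_i and membrane capacitance C_m. V is the
depolarization from rest (rest = 0 mV). The gating rate functions are
the standard 1952 squid-axon forms in this convention:

    α_n = 0.01(10−V)/(e^{(10−V)/10}−1)   β_n = 0.125 e^{−V/80}
    α_m = 0.1(25−V)/(e^{(25−V)/10}−1)    β_m = 4 e^{−V/18}
    α_h = 0.07 e^{−V/20}                 β_h = 1/(e^{(30−V)/10}+1)

with constants C_m = 1 μF/cm², ḡ_K = 36, ḡ_Na = 120, g_L = 0.3 mS/cm²,
V_K = −12, V_Na = 115, V_L = 10.613 mV, R_i = 34.5 Ω·cm. V_L is the
usual equilibrating value: the total ionic current at rest is
−0.004 μA/cm², so rest is stationary to within 0.02 mV over 100 ms.
The removable singularities of α_n (V = 10) and α_m (V = 25) are filled
by their series limits within |ΔV| < 10⁻⁶ mV.

## Drive and noise

The deterministic signal is a constant current density μ applied
indefinitely on an end segment [0, x_sig) — heuristically the
soma-dendritic input region, with the rest of the cable playing the
axon. Stochastic input lives on an independent window and comes in two
forms:

* **Additive**: two-parameter white noise in the voltage equation. The
  discretized increment per node and step is σ √(Δt/Δx)·z with z i.i.d.
  standard normal — the white-noise measure of one space–time cell,
  divided by the cell width. Nodes outside the noise window receive no
  stochastic increment at all (no random numbers are drawn for them).
* **Conductance-based**: the applied current is replaced by
  g_e(V_E−V) + g_i(V_I−V), where each conductance field follows an
  independent per-node Ornstein–Uhlenbeck process
  dg = (ḡ−g)/τ dt + σ_g √(Δt/Δx) z, clamped at zero (the diffusion
  approximation is not sign-constrained; conductances are). The
  conductance equations carry no spatial coupling. Defaults:
  excitatory-only, τ_e = 2 ms, V_E = 80 mV above rest. These synaptic
  constants are plausible rather than calibrated; with them the
  repetitive-firing threshold in ḡ_e comes out at ≈ 0.114 mS/cm²
  (equivalently ≈ 9 μA/cm² of drive at rest, the same scale as the
  critical current density).

Windows are given in cm and snapped to grid nodes as half-open
intervals [x0, x1): abutting windows share no node, so "disjoint"
signal and noise are disjoint exactly, node by node. Overlap fractions
are computed by interval arithmetic, |signal ∩ noise|/|signal|.

## Integration scheme

Fully explicit forward Euler–Maruyama on a uniform grid: second
differences with mirror ghost nodes at the sealed ends (a spatially
constant field maps exactly to zero, and a spatially uniform run
reproduces the point-model ODE trajectory node for node to < 10⁻⁶ mV),
all reaction terms evaluated at the current time level, gating clamped
to [0,1] after each step (forward Euler can overshoot under
noise-driven excursions). The stability ratio r = D Δt/Δx² must stay
below 1/2 (hard error; warning above 1/4); the default grid has
r ≈ 0.043. A trajectory leaving |V| ≤ 500 mV raises an error naming
the node and time.

Two code paths produce identical trajectories from the same seed: a
vectorised numpy single-step reference, and a compiled (numba) kernel
that advances many steps per call consuming pre-drawn normal blocks in
the same stream order. The test suite asserts their agreement; long
runs use the kernel (~0.3–0.4 s per 100 ms trial on one CPU).

## Geometry and calibration

Grid constants: Δx = 0.01 cm, Δt = 0.01 ms, L = 4.5 cm, evaluation time
t_end = 100 ms. The single calibrated knob is the fiber radius,
a = 3.0×10⁻⁵ cm (≈ 0.6 μm diameter), giving D ≈ 4.35×10⁻⁴ cm²/ms and an
electrotonic length constant λ = √(a/(2 R_i g_L)) ≈ 0.038 cm, so the
0.1 cm signal window spans ≈ 2.6 length constants. This one choice
jointly fixes the cable thresholds near the space-clamped value:

* repetitive-firing onset (final-time count ≥ 5) at μ = 6.7 for
  x_sig = 0.1 and μ = 6.3 for x_sig = 0.2, versus ≈ 6.2–6.4 in the
  point model;
* doublet onsets (count exactly 2 on a 0.5-step scan) at μ = 6.5
  (x_sig = 0.1) and μ = 6.0 (x_sig = 0.2);
* conduction speed ≈ 0.042 cm/ms, so the first emitted spike sits at
  x ≈ 4.2 cm at t_end — it "almost reaches" the far end, and later
  spikes are all still on the cable when counted.

t_end = 100 ms was set together with this: at onset the source fires at
≈ 50 Hz, so a 100 ms window is the shortest evaluation period in which
a just-critical train can reach the 5-spike criterion. The `hhcable
calibrate` subcommand re-derives the threshold table for a list of
radii if the geometry is changed.

## Spike counting

A spatial profile V(x) is scanned for maximal contiguous runs above a
threshold of 45 mV over rest; runs whose peaks are closer than 10 Δx
merge into one spike (a plateau dipping briefly below threshold is one
spike, not two). HH spike peaks are 90–110 mV and subthreshold
fluctuations stay under ~20 mV, so any threshold in 30–60 mV yields the
same count on clean trains — the counting rule has no tuned parameter
in practice. Deterministic sweeps may take the maximum count over
snapshots; all stochastic experiments count on the final field only,
so spikes annihilated by noise-nucleated secondary waves before t_end
are correctly not counted. Time series V(t) at fixed positions are
reduced to upward threshold crossings separated by a 2 ms refractory
gap.

## Experiments and statistics

Every stochastic design point runs 50 independent trials. Summaries
report the mean count, a normal-approximation 95% half-width
(1.96·s/√n), and the interference fraction — the fraction of trials
with strictly fewer spikes than the noise-free run of the same
configuration. Per-trial seeds derive from (base seed, experiment
label, sweep value, trial index) via SeedSequence, so results are
reproducible and sweep points independent.

The repetitive-firing criterion everywhere is a count of ≥ 5 (at the
final time for the cable, within 100 ms of sustained drive for the
point model): the noise-free count jumps abruptly from ≤ 2 to ≥ 6
across the onset, so any cut between the branches locates the same
threshold.

Design points chosen where the source material leaves them open:

* ISR curves use whole-cable noise at the critical drive and a σ grid
  spanning 0–0.3; the "well below critical" reference is μ = 4.0.
* The overlap experiment fixes x_sig = 0.2 at its critical drive
  μ = 6.3 with weak noise σ = 0.1 and slides a 0.2 cm noise window from
  exact overlap to disjointness. Interference is zero below 40%
  overlap (right at the 40% boundary one or two trials in 50 may fail) and
  rises monotonically to ≈ 0.6–0.7 at full overlap. The
  full-overlap fraction scales with the number of noise-free spikes at
  the evaluation time (6 here): each spike is an independent
  opportunity for failure, so longer evaluation windows give larger
  fractions.
* The disjoint-noise invariance uses σ ∈ {0.1, 0.2, 0.3} — the
  weak-noise regime. This is a sharp, exact statement: every one of 50
  trials returns exactly the noise-free count, even with noise on 84%
  of the cable. It genuinely breaks at larger amplitudes (σ ≈ 0.4–0.5),
  where noise nucleates spike pairs far from the signal whose
  left-going members annihilate oncoming spikes; the suite asserts
  this secondary-wave regime separately.
* The interior-excitation control shortens the evaluation to 50 ms so
  that no spike from a mid-cable stimulus reaches either end. An
  interior window feeds waves in both directions, doubling the axial
  load, so its repetitive onset sits near μ ≈ 8.0–8.5 (vs 6.7 at the
  sealed end); the default drive 8.2 is just above it. The noise-free
  response is symmetric (equal counts both sides), co-located weak
  noise cuts the count by >30%, and disjoint noise changes nothing —
  the effect does not depend on the stimulus abutting a boundary.

## Verification

The integrator is checked against independent references rather than
against itself: the space-clamped path against an adaptive RK45
solution (< 1 mV sup-norm on a subthreshold trajectory); the cable
against the point model in the zero-gradient limit (< 10⁻⁶ mV); pure
diffusion against brute-force iterated-stencil convolution (< 10⁻¹⁰);
the discrete OU update against its closed-form stationary variance
σ²(Δt/Δx)/(1−(1−Δt/τ)²) to 1% over 10⁵ steps; the passive cable
against the analytic sealed-end steady state (piecewise cosh, < 1%);
and grid refinement (Δx, Δt halved) moves the deterministic spike
count by at most 1.

## What the synthetic conditions do and do not show

All inputs are generated internally; there is no recorded data. The
model is the uniform unmyelinated squid-axon cable: no branching, no
soma/axon inhomogeneity, no channel-number stochasticity, no
temperature dependence, and the noise is white in space and time (or
OU in time, white in space) rather than shaped by real synaptic
anatomy. Passing tests therefore demonstrate properties of the HH
reaction–diffusion system under these idealized drives — in
particular that the generation/propagation asymmetry under weak noise
is a robust feature of the equations, not an artifact of grid,
boundary, or end-placement of the stimulus (the interior-excitation
control). They do not quantify how large the effect is in any real
neuron. Quantities tied to the evaluation window (absolute spike
counts, interference fractions) scale with t_end; threshold locations
(6.2–6.7 μA/cm²) and the qualitative ISR/overlap structure do not.

## Known limitations

* Forward Euler is first-order; thresholds shift by ~0.1 μA/cm² under
  step refinement (within the reported resolution).
* The conductance-mode synaptic constants are representative, not
  fitted; conductance results are reported as regimes, not calibrated
  values.
* The interference fraction compares each trial to a single
  deterministic reference count; it does not distinguish losing one
  spike from losing four (the mean-count curves carry that
  information).
* No collision detector: secondary-wave annihilation is observed only
  through its effect on the final count.
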