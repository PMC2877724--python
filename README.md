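# hhcable

Stochastic spatial Hodgkin–Huxley cable simulation: weak noise can stop
action potentials from being *generated*, but not from *propagating*.

Many neurons fire almost periodically, and the onset of such repetitive
firing in the Hodgkin–Huxley (HH) model is abrupt: below a critical
drive the membrane emits at most one or two spikes, above it an
indefinite train. Near that onset the system is exquisitely sensitive —
a small amount of noise *reduces* the mean firing, and the mean spike
count passes through a minimum as the noise amplitude grows (inverse
stochastic resonance, ISR). A point-neuron model cannot ask *where* the
noise acts. This package simulates the full spatial HH cable so that
the deterministic drive (a stand-in for somatic input) and the noise
occupy independent windows along the fiber, which may overlap fully,
partially, or not at all. The headline phenomenon: noise overlapping
the signal region suppresses spiking, while the same noise on a
disjoint stretch of cable — even most of it — leaves every spike
untouched.

## Model

Membrane depolarization V(x,t) (mV above rest) on a cable of length L
with sealed (zero-flux) ends obeys

    C_m ∂V/∂t = (a / 2R_i) ∂²V/∂x² − I_ion(V,n,m,h) + I(x,t)
    I_ion = ḡ_K n⁴ (V−V_K) + ḡ_Na m³h (V−V_Na) + g_L (V−V_L)

with the standard 1952 squid-axon gating kinetics dx/dt = α_x(V)(1−x) −
β_x(V)x for x ∈ {n,m,h}. The applied current is

    I(x,t) = μ·1[0 ≤ x < x_sig] + σ·1[noise window]·ξ(x,t)

where ξ is two-parameter (space–time) white noise; the explicit
finite-difference Euler–Maruyama scheme adds σ√(Δt/Δx)·z per node and
step inside the noise window. A conductance-based mode instead replaces
the applied current by g_e(V_E−V) with g_e an Ornstein–Uhlenbeck
process per node (the diffusion approximation of synaptic input).

The response variable is N, the number of spikes standing on the cable
at the evaluation time (supra-threshold excursions of the V(x)
profile), with the geometry arranged so the first emitted spike has
almost reached the far end by then.

## Worked example

Locate the repetitive-firing onset for the 0.1 cm end window and trace
the ISR curve at that drive:

```
$ hhcable find-critical --x-sig 0.1
critical mu (x_sig=0.1) = 6.7

$ hhcable isr --x-sig 0.2 --seed 1 --sigmas 0,0.05,0.1,0.15,0.3
using critical mu = 6.3
 sigma  mean_spikes     ci95  interference_fraction  noise_free_count  n_trials
  0.00         6.00 0.000000                   0.00                 6        50
  0.05         4.12 0.470667                   0.70                 6        50
  0.10         4.28 0.491526                   0.62                 6        50
  0.15         4.44 0.485491                   0.56                 6        50
  0.30         5.28 0.340819                   0.40                 6        50
```

Reading the table: without noise the critical drive μ = 6.3 μA/cm² on
the 0.2 cm end segment sustains a train of 6 spikes on the cable at
t = 100 ms. Whole-cable white noise of amplitude σ = 0.05 *removes*
nearly a third of the spikes on average (interference in 70% of
trials), and the mean count recovers toward the deterministic value as
σ grows to 0.3 — the ISR minimum. Moving the same noise to a window
disjoint from the signal segment (`hhcable overlap`) restores exactly
the noise-free count in every trial.

(The `--sigmas` flag selects a reduced grid for this excerpt; the
default grid is {0, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3}.)

## Layout

- `src/hhcable/membrane.py` — HH kinetics and the space-clamped (point) model
- `src/hhcable/cable.py` — explicit Euler–Maruyama cable integrator (numba kernel)
- `src/hhcable/stimulation.py` — signal/noise windows, OU conductances
- `src/hhcable/spikes.py` — spatial and time-domain spike detection
- `src/hhcable/experiments.py` — sweeps, threshold searches, Monte-Carlo designs
- `src/hhcable/config.py`, `cli.py` — YAML configs, manifests, CLI
- `docs/methods.md` — modeling choices, calibration, limitations
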