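# Model and methods

## The circuit

`tadcpg` implements a minimal conductance-based model of the spinal
central pattern generator (CPG) that drives swimming in hatchling
*Xenopus* tadpoles. Each body side ("half-centre") contains one
excitatory descending interneuron (dIN) and one inhibitory commissural
interneuron (cIN). Six graded synapses wire them up:

- each dIN excites itself through a slow NMDA synapse (a stand-in for
  the mutual excitation of the dIN population that a single model
  neuron cannot provide),
- each dIN excites its ipsilateral cIN through a fast AMPA synapse,
- each cIN inhibits the contralateral dIN through a glycinergic
  synapse whose strength `w_inh` is the principal control parameter.

The state space has 34 dimensions: per side, a dIN with membrane
potential and five gating variables (`m, h` sodium, `f` fast
potassium, `l` slow potassium, `r` calcium), a cIN with four gating
variables (no calcium), and open/close state pairs for the three
synapses originating on that side. The left block occupies indices
0–16 and the right block 17–33, so the mid-line reflection is a fixed
permutation and the vector field is Z2-equivariant whenever the two
sides carry identical parameters. The in-phase subspace
Y+ = {y_L = y_R} is then invariant, and the package integrates exactly
symmetric episodes on the explicit 17-dimensional restriction (the
"half system") so that this invariance holds exactly rather than to
solver round-off.

## Equations

Membrane potentials follow single-compartment Hodgkin–Huxley dynamics,
`C dv/dt = Σ i`, with C = 10 pF and all currents written
depolarizing-positive in pA (conductances nS, voltages mV, times ms).
Leak, Na (m³h), fast K (f^k) and slow K (l^j) currents are ohmic;
the dIN calcium current uses the Goldman–Hodgkin–Katz constant-field
form with the gate squared. Two conventions close the GHK term
dimensionally: the voltage is converted to volts only inside the
exponent μ = 2Fv/(RT), and the numeric value of the expression is read
in pA with the sign chosen so that calcium influx (external
concentration 10⁻⁵ mol/cm³ against internal 10⁻⁷ mol/cm³)
depolarizes. At v = 0 the analytic limit is evaluated whenever
|μ| < 10⁻⁶, so the current is continuous there.

Gating variables obey `dx/dt = α(v)(1−x) − β(v)x` with every rate in
the five-coefficient form `(A + Bv)/(C + exp((D + v)/E))`; an
overflowing exponential saturates the denominator and the rate goes to
zero. Synapses are graded: transmitter release is a sigmoid of the
presynaptic potential saturating at `T_s`, and each synapse carries a
fast "open" and a slow "close" variable whose difference gates the
postsynaptic current; the NMDA current is additionally multiplied by
the magnesium-block sigmoid `1/(1 + 0.05 exp(−0.08 v))`.

Episodes are initiated from the settled resting state by step currents
of amplitude `A` (nA) and duration `d` (ms) to the two dINs, the right
one delayed by `Δ` ms; arbitrary extra step currents to any neuron
support the single-cell and mid-cycle protocols.

## Channel kinetics: provenance and calibration

The neuron-level constants (Table values: conductances, reversal
potentials, gating powers, calcium constants, synaptic time constants,
release thresholds) are taken verbatim from the published model
description and live in `src/tadcpg/data/default_params.yaml`. The
A–E rate coefficients of the nine gating variables are not printed in
the main text; the packaged values were constructed in the same
functional form and calibrated so that the model reproduces the
documented behaviour of the original:

- dIN resting potential near −50 mV with a firing threshold only a few
  millivolts above rest, so a 10 pA, 6 ms pulse initiates an episode
  while a 2 ms pulse does not (this fixes the structure of the
  initiation-space maps);
- a post-inhibitory rebound spike on release from hyperpolarizing
  current injected against a depolarized background, with sodium
  de-inactivation as the underlying mechanism;
- spike overshoot beyond +20 mV (the synaptic release sigmoids are
  centred at +10 mV and would otherwise never activate);
- a dIN→cIN first-spike lag of ≈4–5 ms;
- swimming at ≈50 ms period for strong inhibition (w_inh = 60 nS at
  w_ampa = w_nmda = 10 nS), in-phase rhythm at ≈19 ms for w_inh = 28,
  and a ≈45–49 ms cycle at w_inh = 42.

Two design features of the calibrated kinetics deserve note. First, a
low-threshold calcium activation (`r`, half-activation ≈ −44 mV) is
the subthreshold amplifier that gives the dIN its low, sharp
threshold; the GHK driving term saturates with depolarization, so the
mechanism is self-limiting. Second, sodium inactivation is steep
enough that the steady-state current–voltage curve is monostable:
without it, the low threshold creates a spurious stable depolarized
equilibrium that traps the dynamics after a spike. A consequence of
that steepness is that the dIN is refractory through the depolarized
half of each swim cycle, which is why the mid-cycle current-pulse
switching protocol (see below) evokes no extra spike in this
parameterization.

## Attractor classification

Spikes are upward crossings of 0 mV with a 2 ms lockout, linearly
interpolated between samples (output grid 0.1 ms). The tail window of
an episode (default last 500 ms of a ≥3 s run) is classified from the
two dIN trains:

- **rest** — fewer than 5 spikes on either side (period 0);
- **sync** — left/right offsets below ε·T with one spike per cycle;
- **swim** — offsets within ε·T of half the firing interval;
- **sync2** — double-period synchrony: alternating inter-spike
  intervals (two spikes per full cycle) with small offsets whose sign
  alternates as the sides take turns leading;
- **other** — anything else.

ε = 0.1 of the period by default. The period is the median ISI, or
the sum of consecutive ISI pairs when the ISIs alternate. ISI
alternation is declared when the even/odd ISI groups separate by more
than 8% of the mean ISI *and* 1.5× the summed within-group spread;
the thresholds were set against a generative oracle of jittered
rest/sync/swim/sync2 templates, which the classifier must recover in
≥99% of 1000 random draws (it scores 100% at per-spike jitter up to
half the phase tolerance). Transitions between regimes are located
with 100 ms sliding windows at 20 ms stride.

## Numerical choices

Deterministic runs use LSODA with rtol = atol = 10⁻¹⁰ (10⁻¹² available
via the solver config), with the integration restarted at every
stimulus edge so the adaptive solver never steps across a
discontinuity; output is sampled on a 0.1 ms grid. Exactly symmetric
episodes run on the 17-dimensional half system (see above); the full
and half systems agree cycle-for-cycle to <0.02 ms in the ISIs, while
the absolute first-spike latency is ill-conditioned (a near-threshold
tangency) and may shift by a few tenths of a millisecond between the
two routes. Stochastic episodes use Euler–Maruyama with dt = 0.01 ms
and equal noise amplitude φ on all 34 components; gating and synaptic
variables are clipped to [0, 1] after each step (clip counts are
reported in the trajectory metadata and are negligible at φ = 0.01).
The resting state is found by settling for 500 ms and Newton-polishing
to a field norm below 10⁻⁸ per component, then symmetrized exactly.

Stability boundaries are located by bisection on a synaptic weight
with the predicate "the tail classifies as the target category";
near-boundary runs are lengthened (default 8 s) because transients
diverge near subcritical bifurcations. Numerical continuation of
unstable branches is out of scope; every boundary reported here is an
attractor-based, simulation-plus-bisection surrogate.

## Problem sizes

The shipped analysis scripts and the test suite use scaled-down
instances chosen to characterize each result while remaining cheap:
initiation-space and parameter-plane grids default to 16×16 and 6×3
respectively (the full-resolution maps are the same computation at
n = 128 and longer horizons, available through the CLI flags),
stochastic ensembles default to 100 replicates of 2 s, and per-pixel
episodes run 2–3 s of model time with a convergence window at the
tail.

## Known limitations

- The reconstructed kinetics shift the quantitative bifurcation
  boundaries: swimming persists down to w_inh ≈ 5.1 nS (rather than
  ≈8.6) and the in-phase rhythm remains stable inside the symmetry
  manifold down to ≈9 nS (rather than ≈15.7) at w_ampa = 12 nS.
- The in-phase cycle is transversally unstable for w_inh in [22, 35]
  at w_ampa = 12 nS, so the upper synchrony boundary and the
  criticality-switch point on it do not exist as bisectable objects in
  this calibration; near-symmetric starts escape to swimming within
  0.15–0.4 s. This makes noise-driven synchrony→swimming transitions
  robust (≈98% of noisy in-phase starts at w_inh = 22.2 reach swimming
  within 2 s) but removes the bistable synchrony band away from the
  manifold.
- A lone dIN with its self-NMDA synapse is a slow pacemaker once
  kicked, so very weak inhibition leaves a phase-frozen oscillation
  rather than a return to quiescence; the swim/rest boundary is
  therefore absent along some parameter rows.
- Mid-cycle pulse switching (swim → synchrony bout → swim) is absent,
  as discussed under calibration.
- Gaussian state kicks use sd = 10⁻³ on every component; synaptic
  conductance symmetry breaking uses absolute sd in nS by default with
  a relative mode available.
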