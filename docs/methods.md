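# Methods

## The Kv1.3 gating model

Kv1.3 gating is modeled as a single linear chain of discrete states

    C1 ⇌ C2 ⇌ C3 ⇌ C4 ⇌ O ⇌ I

with macroscopic (expected-occupancy) semantics: the state vector p(t)
evolves as dp/dt = p·Q(V), where Q is the transition-rate (generator) matrix
assembled from six rates. The four voltage-dependent rates are single
exponentials of voltage,

    α = a·exp(V/m)      closed→closed forward (activation)
    β = b·exp(−V/n)     closed→closed backward (deactivation)
    η = c·exp(V/p)      O→I (C-type inactivation)
    φ = d·exp(V/q)      I→O (recovery)

and A (C4→O) and B (O→C4) are voltage independent. Defaults are the
published ten-constant set (a=0.448, b=0.043, c=0.003, d=0.00008,
A=280.035, B=1.648 ms⁻¹; m=27.530, n=17.528, p=174.961, q=1016.330 mV).
All rates, the chain length, per-edge multiplicities and the sign of each
voltage exponent are configuration fields.

Because protocols are piecewise constant in voltage, propagation uses the
matrix exponential per segment (exact up to floating point); an explicit
Euler integrator at dt = 1 µs serves as an independent oracle in the tests
(agreement ≤ 1e-6 on all states over 100-ms segments). Long conditioning or
inter-sweep rests (60–90 s experimentally) are replaced by the analytic
stationary distribution of Q at the holding voltage, which is exact for this
purpose and orders of magnitude faster; the equivalence is spot-checked by
direct integration.

### Topology calibration

The published figure defines the chain qualitatively but not the number of
closed states or per-edge multiplicities, and those choices move the summary
kinetics by tens of millivolts. We therefore selected the topology by
simulating the full protocol/fit pipeline over a grid of linear chains
(2–6 closed states; uniform, mixed and Hodgkin–Huxley-style 4α/3α/2α/α
multiplicities; both signs of the φ exponent) and scoring against the four
published summary statistics (activation V₅₀ = −28.4 mV, availability
V₅₀ = −43.5 mV, recovery τ = 8.6 s at −45 mV and 14.6 s at −90 mV).

The shipped default is four closed states with backward multiplicities
(3, 2, 3) on the closed–closed steps — i.e. cooperative re-closing — which
reproduces all four targets simultaneously (−27.9 mV, −44.9 mV, 8.1 s,
13.9 s). A plain chain with unit multiplicities puts the activation midpoint
near −36 mV and cannot reach −28 mV for any chain length ≤ 6, because the
equilibrium constant of the opening step (A/B ≈ 170) pulls the curve
leftward; backward-weighted closed transitions compensate. For φ we use
exp(+V/q): with q ≈ 1016 mV the voltage dependence is negligible either way
(recovery is weakly voltage dependent), but the + sign lands the −90 mV
recovery constant at 13.9 s versus 11.6 s for the − sign, the former
matching the measured 14.6 s. The faster, incomplete recovery at −45 mV
(plateau ≈ 0.5) needs no extra mechanism: it falls out of re-inactivation
through the small open-state occupancy near the availability midpoint.

The fitted activation slope (5.6 mV) and availability slope (3.9 mV) are
somewhat shallower/steeper than the measured 4.9 / 3.0 mV; the midpoints,
not the slopes, were the calibration targets.

## Voltage-clamp protocols and analysis

The four protocol builders mirror standard practice: activation (1-s steps
−70…+50 mV by 15 mV, holding −90 mV), steady-state inactivation
(conditioning −80…−10 mV by 5 mV to steady state, 150-ms test at +50 mV),
deactivation (7-ms pre-pulse to +50 mV, 30-ms tails −100…−30 mV by 10 mV;
the tail duration is our choice, ample for the sub-ms–ms tails), and
two-pulse recovery (P1 1 s at +50, variable gap, P2 150 ms at +50). The
interpulse grid is not published; we use 10 log-spaced intervals from 0.25
to 60 s. Macroscopic current is I = N·g·P_o·(V−E) with g = 15 pS and
E = −73 mV; the default sampling interval is 0.05 ms (20 kHz).

Peak detection takes the largest-magnitude sample in a segment after
skipping the first two samples (guarding the instantaneous step transient).
Boltzmann and exponential fits are multi-start Levenberg–Marquardt least
squares (five log-spaced τ initializations); fractional recovery is fitted
as f(t) = plateau − (plateau − f₀)·e^{−t/τ} with a free plateau, since the
−45 mV curve saturates below 1 and a forced plateau would bias τ.

## The T-cell model

The non-excitable T cell is modeled with four conductances:

    C_m dV/dt = I_inj − (I_TASK + I_CRAC + I_Kv1.3 + I_IK)

with C_m = 1.5 pF, V(0) = −55 mV, G_TASK = 0.13 nS (E = −100 mV),
G_CRAC = 0.09 nS (E = +80 mV), G_IK = 0.11 nS (E = −75 mV), and Kv1.3 as
N·g·P_o(V) with E = −73 mV. CRAC is conductive throughout (store-depleted
condition); TRPM7, swelling-activated Cl⁻ and TRPC channels are outside the
model's scope. The imposed rest of −55 mV is an initial condition, not an
equilibrium of these conductances. Local Ca²⁺ near the CRAC mouth follows

    d[Ca]/dt = −e_trans·I_CRAC − e_diff·[Ca]

(e_diff = 0.003 ms⁻¹), so a clamped voltage gives the closed-form plateau
(e_trans/e_diff)·|I_CRAC|. Global (cell-averaged, nM-scale) Ca²⁺ is taken
proportional to local Ca²⁺, normalized so the control cell (4.5 nS Kv1.3,
15 pA injection) reaches 0.5 µM at the 10-s readout. IK open probability is
a Hill function of global Ca²⁺. Initial Ca²⁺ is 0 (configurable).

Integration is operator splitting per step: exact matrix-exponential gating
update at the frozen voltage (propagators precomputed on a 0.1-mV grid and
linearly interpolated — an interpolation of row-stochastic matrices, so
probability is conserved exactly), the exact exponential update of the
linear Ca²⁺ ODE, then an explicit voltage step. Default dt = 0.05 ms;
halving dt changes V(10 s) by ~1e-5 mV. A per-step |ΔV| > 5 mV triggers
automatic dt refinement (error if a 1e-4 ms floor is reached). Simulations
in the test suite use dt = 0.1 ms, which is converged at the readout
precision used.

### Calibration of the Ca²⁺/IK branch

Two quantities are not published as formulas and were calibrated, once,
against the five printed (G_Kv1.3, V at 10 s, Ca at 10 s) triples:

* **IK Hill curve** — midpoint 0.8 µM, coefficient 4 (grid-searched with the
  local→global ratio recalculated self-consistently per candidate). The
  published source for this curve gives no printed parameters; the values
  are within the plausible range for K_Ca3.1. Result: V(10 s) = +36.7,
  +19.8, −1.4, −33.9, −43.2 mV for 0.4, 2, 4.5, 9, 22.5 nS (printed: +35.7,
  +19.8, −0.62, −35.9, −43.1), strictly monotone in Kv1.3 expression.
* **e_trans** — the printed 0.006 µM·pA⁻¹·ms⁻¹, combined with the printed
  steady-state voltages, overshoots the printed Ca²⁺ plateaus by almost
  exactly 2×. `CaParams.calibrated()` therefore uses e_trans = 0.003 —
  consistent with reading the transfer coefficient per unit charge rather
  than per divalent ion — giving plateaus 3.9, 5.4, 7.3, 10.3, 11.1 µM
  (printed: 3.48, 4.89, 7.01, 10.47, 11.48; all within 12%). Plain
  `CaParams()` keeps the printed 0.006, with κ_global adjusted so the global
  signal (and hence IK, and hence the voltage trajectory) is identical.

The 10-s readout time is fixed; note that at −43 mV the inactivation time
scale (~8 s) is comparable, so these "steady-state" values are still slowly
drifting readouts, in the model as in the experiment.

## Parameter estimation

The objective is the summed squared difference between simulated and
observed currents over all sweeps and families, with the per-family
amplitude N·g profiled analytically (non-negative least squares in one
scalar). Rates are searched in log10 space (they span 0.00008–280 ms⁻¹):
a particle swarm (default 20 particles, inertia 0.7, cognitive/social 1.5)
followed by per-coordinate golden-section passes. Failures inside a
candidate simulation return a large finite penalty. Fixed seeds give
bit-identical results. The test suite documents an identifiability caveat
honestly: the recovery constants (d, q) are essentially unconstrained by
activation data alone and require a two-pulse family in the problem.

## Synthetic data

The generator produces the deterministic model current plus i.i.d. Gaussian
noise at a 20 kHz-like sampling rate, with the generating parameters
serialized next to the data. It does not emulate the 2.9 kHz Bessel filter
of a real rig (noise is white, not colored), series-resistance or capacitive
artifacts, leak, or cell-to-cell variability. Passing recovery tests on
these fixtures therefore demonstrates correctness of the estimation
machinery, not robustness to every artifact of real recordings.

## Known limitations

* Macroscopic expectation only; no single-channel (stochastic) simulation.
* No temperature dependence; no state-dependent toxin kinetics — block is a
  pure reduction of channel count.
* The chain topology is a calibrated effective description: other
  topologies can fit the same four summary statistics, and single-channel
  data would be needed to discriminate them.
* CRAC has no store/STIM dynamics; the osmotic-swelling pathway is not
  modeled.
* Boltzmann slopes are reproduced only approximately (see above).
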