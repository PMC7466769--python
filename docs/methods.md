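# Model and methods

`cardioloop` simulates the human cardiovascular system with a single
contractile element: a ventricular myocyte model produces an intracellular
Ca²⁺ transient, the Ca²⁺ drives a half-sarcomere cross-bridge model, the
half-sarcomere's wall stress pressurizes an idealized hemispherical
ventricle, and the ventricle pumps blood around a closed five-compartment
systemic circulation.  Coupling is strictly one-way (electrophysiology →
contraction → hemodynamics); there is no mechano-electric feedback.

## Myocyte electrophysiology

The membrane model is the ten Tusscher-type human mid-myocardial (M cell)
ventricular myocyte: nine channels, four pumps, two exchangers, 17 state
variables (membrane voltage, 12 gates, cytosolic/SR Ca²⁺, Na⁺, K⁺).  All
constants are held at their published values except six that are plausible
pharmacological targets and are exposed as multiplicative factors: the SR
leak rate (`Ca_Vleak`), the maximal SERCA uptake rate (`Ca_Vmaxup`), and
the conductances `g_CaL`, `g_to`, `g_Kr`, `g_Ks`.

Pacing uses 3 ms pulses of −52 pA pF⁻¹ at 1 Hz.  Because the uncoupled
myocyte needs several hundred beats to reach its limit cycle, coupled
simulations start from a pre-computed steady state (1000 pre-paced beats,
electrophysiology only — consistent with the one-way coupling).  The
integrator is a hybrid scheme: exponential (Rush–Larsen) updates for the
gates — which therefore remain in their admissible ranges without clamping
— and forward Euler for voltage and concentrations, with 0.25 ms sub-steps
refined to 0.025 ms whenever a trial step moves the voltage by more than
0.5 mV.  Against an adaptive stiff integrator (LSODA) run on the same
equations, the hybrid scheme agrees to ≈0.2% RMS of dynamic range for both
voltage and the Ca²⁺ transient at 1 Hz.  Two guards exist purely for
extreme parameter sweeps: cytosolic and SR Ca²⁺ are floored at 10⁻⁹ mM
(forward-Euler overshoot at 0.1× SERCA activity would otherwise drive the
SR negative), and the Ca-gated inactivation gate is validated against the
supremum of its published steady-state expression (1.53/1.46, slightly
above 1) rather than 1.

## Half-sarcomere

The contractile unit is a dynamically coupled myofilament model.

**Thin filament.**  A fraction `N_on` of binding sites is active:

    dN_on/dt = k_on [Ca] (N_ov − N_on)(1 + k_coop N_on)
             − k_off (N_on − N_bound)(1 + k_coop (N_ov − N_on))

Bound cross-bridges protect their sites from deactivation, and the
cooperative terms steepen both activation and shut-off.  `N_ov` is the
length-dependent overlap fraction described below.

**Thick filament.**  Myosin heads occupy an OFF (super-relaxed /
interacting-heads motif) state, an ON state, and a strain-resolved bound
force-generating (FG) state.  The OFF→ON rate rises linearly with total
wall stress, `J1 = k_1 (1 + k_force max(F, 0))` — force-dependent
recruitment, the mechanism that gives the model its length-dependent
activation and, at the system level, its Frank–Starling behavior.  ON→OFF
is first-order (`k_2`).  Attachment into available sites
(`N_on − N_bound`) is Boltzmann-weighted toward zero strain,
`k_3 exp(−k_cb x²/2k_BT)`, on a fixed strain grid x ∈ [−10, 10] nm with
Δx = 0.5 nm; detachment is `k_4,0 + k_4,1 x⁴`.  Bound heads are advected
along the strain axis when the half-sarcomere changes length (linear
interpolation; heads pushed off the grid return to ON).  Active stress is
`N_0 k_cb Σ M_FG(x)(x + x_ps) Δx`; one ATP is counted per completed cycle
(detachment flux).  All population updates use flux-limited explicit
steps, so head number is conserved to round-off and populations never go
negative.

**Overlap (force–length) function.**  Available thin-filament sites follow
a trapezoid-like shape: an exponential ascending limb with length
constant `w_ascending` (120 nm), shifted to reach exactly zero at
`hsl_zero_overlap` (730 nm), a plateau from `hsl_full_overlap` (1000 nm)
to 1100 nm, and a linear descending limb vanishing at 1500 nm.  Two
properties of this shape matter.  First, the exponential limb has a
near-constant *logarithmic* slope, so the end-systolic elastance scales
gently (roughly proportionally) with contractile strength; a linear limb,
whose log-slope diverges near zero overlap, makes the ESPVR explode by
10–30× under moderate contractility changes, which is incompatible with
the moderate relative sensitivities this class of model reports.  Second,
the true zero below 730 nm lets an over-contracting ventricle lose force
entirely, producing the graceful "squeezed dry, low output" collapse at
high `k_1` rather than a locked high-pressure state.

**Passive stress** is the titin-like exponential
`σ (exp((l − L_slack)/L) − 1)` above slack length, zero below (no
compressive element).

## Ventricle and circulation

The ventricle is a hemisphere of chamber volume V with incompressible wall
volume W: internal radius `r = (3V/2π)^(1/3)`, wall thickness
`t = W/(2πr²)`.  Chamber pressure uses the thick-shell Laplace form

    P = 2 S ln(1 + t/r),

which reduces to the thin-wall `2 S t / r` to first order in t/r
(within ~10% throughout the normal beat) but stays logarithmically bounded
when the over-contracting chamber becomes thick-walled; the literal
thin-wall formula diverges as 1/V there and permanently locks extreme
sweep runs at 10⁶–10⁷ mmHg.  The half-sarcomere length is slaved to the
chamber volume through the mid-wall circumference, with the mid-wall
radius defined by the volume enclosed at mid-wall,
`r_mid = (3(V + W/2)/2π)^(1/3)` — identical to `r + t/2` to first order
but monotone in V down to an empty chamber.  The cavity cannot be squeezed
below a residual volume (8 mL, `V_residual`), representing the residual
cavity of a real ventricle; this also keeps the wall geometry well-defined
and diastolic refilling possible in every sweep regime.

The systemic circulation is a series loop of five zero-dimensional
compartments (aorta, arteries, arterioles, capillaries, veins) with
`P_x = V_x/C_x` and Ohm's-law flows through one resistance per connection.
One-way valves rectify ventricular outflow (aortic) and inflow (venous
return); isovolumic phases emerge whenever both valve flows are zero, not
from a mode switch.  Volume updates are exact bookkeeping: total blood
volume is conserved to round-off (≲10⁻¹³ L over 17 beats), and flows are
limited so no compartment can be driven negative.

## Protocol

A standard run spans 17 beats at 1 Hz.  The ventricle starts at 150% of
its slack volume with the remaining blood pooled in the veins; the
circulation fills over the first beats and the system reaches its periodic
orbit in roughly 7–9 beats.  From the start of beat 10 to the start of
beat 15, 60% of the total blood volume (3 L of 5 L) is withdrawn from the
venous compartment at a constant rate, producing six progressively
preload-reduced PV loops.  The ESPVR is the ordinary-least-squares slope
through the end-systolic corner (the sample maximizing P/V) of loops
10–15.  A single-beat ESPVR estimate is also provided: a sinusoid is
fitted to the isovolumic contraction and relaxation segments (equal total
weight per segment; half-period spanning the isovolumic envelope), the
extrapolated peak `P_max,iso` is floored at the observed peak, and the
slope is `(P_max,iso − P_es)/(V_ed − V_es)`.

## Numerics

Outer steps are 1 ms: the stimulus schedule, the electrophysiology
hand-off and the logging cadence all live on this grid.  Within each outer
step the explicit stress→pressure→flow→volume→length coupling is
sub-stepped 8× (0.125 ms), with one sarcomere kinetics sub-step per
hemodynamic sub-step.  This matters: at a pure 1 ms explicit coupling the
peak ventricular pressure is ~20% away from the converged solution, while
with sub-stepping, halving the outer step changes steady-state beat
metrics by less than 1%.  The model contains no random numbers anywhere;
identical configurations reproduce bit-identical outputs.

## Parameters and calibration

Published constants (the ionic model, cross-bridge stiffness
k_cb = 1 pN/nm, slack length 900 nm, total blood volume 5 L, pacing
protocol) are used directly.  The remaining sarcomeric kinetic constants,
the overlap-shape lengths, and the circulatory compliances/resistances are
calibration targets: they were tuned — once, at converged numerics — so
the baseline run meets the reference behaviors simultaneously (peak
ventricular pressure in the systolic arterial range, approach to steady
state within ~7–9 beats, ESPVR near 1170 mmHg L⁻¹ from the withdrawal
protocol, a declining ejection-phase force with sustained pressure, and
relative sensitivities of peak/minimum ventricular pressure to `k_1` of
about +0.5/−0.25).  The calibrated file is shipped as
`cardioloop/data/default_config.yaml` and is the package's fixed reference
parameterization; sweeps scale it by multipliers only, preserving
proportional changes.

Sweeps use nine log-spaced multipliers {0.1, 0.178, 0.316, 0.562, 1, 1.78,
3.16, 5.62, 10}.  Relative sensitivity is the slope at multiplier 1 of a
5th-order polynomial fitted against the linear multiplier, normalized by
the fitted value there (`p′(1)/p(1)`, requiring ≥7 valid points including
the base).  Failed or non-physiological runs are flagged, not dropped, and
non-physiological points still contribute to the fits.

## Known limitations

* **Ejection-phase force drop.**  Wall stress falls by ~27% during
  ejection at baseline, not the ~50% this class of model can show.  With
  the log-bounded pressure law, a 50% drop requires an ejection fraction
  near 0.5 at these volumes, which pushes end-systole into the steep
  force–length region and roughly doubles the ESPVR; the ESPVR (an
  explicitly regressed quantity) was prioritized over the approximate
  force-drop figure.
* **Single-beat vs multi-beat ESPVR.**  The sinusoidal single-beat
  estimate runs about 2× the multi-beat regression at baseline: a clamped
  (isovolumic) chamber recruits far more force than an ejecting one in
  this model, so the extrapolated isovolumic peak overstates the
  end-systolic line.  Contractility *ratios* of the single-beat estimate
  are similarly unreliable here, because by 3× `k_1` the model is past its
  collapse threshold.
* **Sharp operating ridge.**  Strong thin-filament cooperativity (needed
  for a quiet diastole) makes baseline function switch-like in the
  activation parameters: several sweep curves change steeply within a
  factor ~2 of base, which inflates some aggregate sensitivity magnitudes
  relative to smoother implementations of the same scheme.
* The usual structural idealizations apply: one ventricle, hemispherical
  geometry without torsion or transmural variation, no atria, no pulmonary
  circulation, no autonomic control, one-way electromechanical coupling,
  a single bound cross-bridge state, and no explicit MyBP-C or
  phosphorylation state variables.

## What the tests show

The test suite verifies the building blocks against independent oracles —
closed-form fixed points (root-finding) for the thin filament, an
independently coded master equation integrated with LSODA for the myosin
subsystem, OLS and polynomial identities for the analytics, an adaptive
stiff integrator for the myocyte — plus the conservation, valve,
determinism and dt-convergence properties of the coupled loop, and the
reproduction of the reference quantitative results at their stated
tolerances.  All inputs are generated by the model itself; nothing here
validates the simulator against experimental recordings, and agreement on
the synthetic protocols does not imply fidelity to any individual heart.
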