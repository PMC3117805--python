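# Model and methods

`cardioloop` is a closed-loop lumped-parameter model of the human
circulation built to study left-ventricular diastolic dysfunction (LVDD)
and its whole-body consequences — in particular why patients can be in
overt heart failure while their ejection fraction looks normal (HFNEF).
This note records the governing equations, the parameter choices and their
provenance, the numerical methods, and the known limitations.

## Cardiac mechanics

Each contractile wall x ∈ {LVF, RVF, SPT, LA, RA} blends a linear
end-systolic and an exponential end-diastolic pressure–volume relation,
weighted by a dimensionless activation e_x(t) ∈ [0, 1]:

    P_x(V, t) = e_x(t) · α(F_con) · E_x,ES · (V − V_x,d)
              + (1 − e_x(t)) · P_x,0 · (exp(λ_x (V − V_x,0)) − 1)

E_x,ES is the end-systolic elastance slope (mmHg/ml), V_x,d and V_x,0 the
zero-pressure volumes of the two relations, λ_x the passive stiffness
(1/ml), and α ≥ 1 a baroreflex inotropic factor applied to the ventricular
walls only.  The instantaneous elastance is the local slope
∂P/∂V = e·α·E_ES + (1−e)·λ·P_0·exp(λ(V−V_0)).

**Septum.** The interventricular septum is a third active pump.  Its
displaced volume V_SPT (positive = bulging into the RV) couples the
chambers through

    V_LV = V_LVF + V_SPT,      V_RV = V_RVF − V_SPT,
    P_SPT = P_LVF(V_LV − V_SPT) − P_RVF(V_RV + V_SPT),

with V_SPT the activation-weighted combination of the inverted septal
systolic and diastolic laws evaluated at P_SPT (the diastolic logarithm is
sign-mirrored for P_SPT < 0).  This fixed point is solved at every
right-hand-side evaluation by damped iteration (damping 0.5, tolerance
1e−6 ml, warm-started from the previous solution; typically ~5–15 sweeps,
with an automatically bracketing bisection fallback).  The solution is
independent of the warm start.

**Pericardium.** All four chambers sit inside a common pericardial sac:

    P_PERI = P_PERI,0 · (exp(λ_PERI (V_heart − V_PERI,0)) − 1) + P_PL,

with V_heart the four chamber volumes plus 6 ml pericardial fluid.
Absolute chamber pressures are transmural wall pressures plus P_PERI.

**Activation functions.** Ventricular and septal activation is a sum of
seven Gaussians A_i·exp(−(t−C_i)²/2B_i²) of the cardiac phase, rescaled so
the cycle maximum is exactly 1.  The width is interpreted as a standard
deviation: under this convention the published coefficient set is
self-normalizing (raw peak 1.0006 for the control set and 1.0022 for the
impaired-relaxation set), which pins the kernel; the alternative 1/e-width
convention is a one-line change in `_core.activation_eval`.  Coefficients
are fixed in absolute time from beat onset, so rate changes lengthen or
shorten diastole only.  Each atrium has a single Gaussian pulse placed
late in the cycle; its width (σ = 0.053 s left, 0.092 s right) and center
(0.06 s before beat end) are calibrated so the control A waves, atrial
filling fraction and venous systolic/diastolic split are physiologic — the
printed atrial elastances would otherwise empty the atria in ~10 ms and
produce nonphysical A-wave spikes.  Because the activation clock resets at
beat onset, e(t) has a small jump there in impaired-relaxation scenarios
(the wide terminal Gaussian has a left tail); waveform indices are sampled
to avoid mistaking that jump for end-diastolic pressure (see below).

## Circulation

Thirteen linear compliant compartments (P = (V−V_un)/C + P_ext) form the
systemic chain AOp → AOd → SA → SAd → SC → SVL → SV → VC and the pulmonary
chain PAp → PAd → PA → PC → PV, closed through the four heart chambers.
Thoracic compartments (AOp, VC, all pulmonary) reference pleural pressure;
the rest reference body pressure (0 mmHg).  Valves are ideal
diode-resistor pairs.  The proximal arterial segments (AOp→AOd, AOd→SA,
PAp→PAd) carry the three inertances.  Three Kelvin "vasoelastic" series
resistances (R_TAO, R_TAOd, R_TPA) sit between the proximal
aortic/pulmonary nodes and their compliances; the node pressures are
obtained in closed form for the open- and closed-valve branches.  A 4
mmHg·s/ml shunt bypasses the pulmonary capillaries, and lumped coronary
(35) and cerebral (16) resistive branches shunt the proximal aorta to the
vena cava.  Blood volume (5000 ml) is conserved identically: every flow
appears once as an inflow and once as an outflow.

Unstressed volumes are not part of the published tables.  Pulmonary V_un
are pinned so the compartments hold the published control volumes at the
published control pressures; the systemic distribution was chosen once,
with the venous reservoir entry (2550 ml) calibrating mean circulatory
filling so the control loop reproduces the published operating point.

## Baroreflex

Structure: proximal aortic pressure → 2 s exponential average (MSAP) →
saturating affine baroreceptor map F_b → affine targets for four efferent
limbs — vagal F_HRv (rises with pressure) and sympathetic F_HRs, F_con,
F_vaso (fall with pressure) — each first-order low-pass filtered (0.5 s
vagal, 2 s sympathetic).  All affine coefficients are identified at load
time by least squares from the model's four published steady-state
operating points; the fits reproduce every printed limb value within 0.02
and the four printed heart rates within 2 bpm.  Effectors:

* chronotropy: HR = h0 + hs·F_HRs − hv·F_HRv (clipped to 30–180 bpm),
  sampled once per beat at beat onset;
* inotropy: α = max(1, 1 + k_α (F_con − 0.40)) on the ventricular E_ES,
  k_α = 2.0 calibrated against the restrictive-scenario RVEF;
* vasomotor tone: distal arteriolar resistance scales by
  1 + 12·(F_vaso − 0.50) and the venous unstressed volume falls by
  500 ml per unit F_vaso above 0.50.  The reference 0.50 places the
  control operating tone above the printed (baseline) R_SA,d, which is
  required for the printed resistance chain to carry the published cardiac
  output at the published pressures; the gains are calibrated to the
  published MSAP column across scenarios.

Because only the four printed steady-state columns constrain the reflex,
transient reflex dynamics (time constants, rate sensitivity of the
baroreceptor) are conventional choices, not data-fitted; only steady
states should be trusted.  `clamp_neural ∈ {con, hr, all}` freezes
individual limbs at control for the feedback-dissection experiments.

## Scenarios

* **IR** (impaired relaxation): terminal activation Gaussian of the LV
  free wall and septum widened (A6 0.516→0.37, A7 0.15→0.249,
  B7 0.04→0.35 s), then re-normalized — relaxation becomes slow and
  incomplete, leaving a positive activation offset at end-diastole.
* **R** (restrictive): λ_LV 0.025→0.05 /ml and λ_SPT 0.05→0.1 /ml.
* **PN** (pseudo-normal): both of the above.
* **R_NSPT**: restrictive free wall with a normal septum.
* **Increased contractility** (combinable with any of the above):
  E_LV,ES and E_SPT,ES scaled by 1.6.

Pleural pressure is −5 mmHg in all runs except the respiratory studies,
where it is −4 − 2 cos(2πt/7) mmHg (extremes −2 and −6, period 7 s).

## Numerics

Adaptive embedded Cash–Karp Runge–Kutta 4(5); mixed error norm with
rtol = atol = 1e−6; step acceptance factor 0.9·err^(−1/5) clipped to
[0.1, 5].  Valve diode kinks are C0-continuous and handled by the step
control (no event localization).  Steps that would drive any stored volume
negative are rejected.  Dense output on a 1 ms grid is produced by landing
step endpoints on grid times.  The cardiac cycle advances beat by beat;
the next period is sampled at each beat onset.  Steady state is declared
when per-beat stroke volume and mean arterial pressure change < 0.5 %
across three consecutive beats (after a 15 s minimum settle), then five
further beats form the analysis window; sinusoidal-pleural runs instead
integrate whole 7 s respiratory cycles (8 by default) and analyze the last
complete cycle.  A run is 60 s of model time at most (56 s respiratory);
one run takes well under a minute on one CPU.  The hot path (model
right-hand side, septal solve, integrator) is numba-compiled; a generic
pure-Python Cash–Karp driver with the same tableau serves as the reference
implementation and is cross-checked against the compiled path in the test
suite.  Halving the tolerance moves steady-state cardiac output by
< 0.2 %, and a ±10 % perturbation of the initial volume distribution
reaches the same attractor to < 0.5 % on all indices.

## Waveform indices

* Valve events: 0.1 ml/s flow-threshold crossings; open intervals closer
  than 0.25 s are merged (inlet valves stay open through diastasis).
* E = first inflow peak after inlet-valve opening; A = last peak before
  closure; boundary at the inter-wave minimum; fused inflow reports A as
  absent.  DT extrapolates a least-squares line on the 70→30 %-of-peak
  descending limb of the E wave to zero flow.  IVRT = outlet-valve closure
  to inlet-valve opening.  RFF/AFF are the filling-volume fractions of the
  E- and A-wave windows.
* End-diastolic pressure is the post-A-wave maximum over the last 150 ms
  of diastole before beat onset (the clinical Z point), sampled strictly
  before onset so the activation-clock reset is not misread as filling
  pressure.
* Venous inflow (flow entering each atrium) is split into S (inlet-valve
  closure → opening), D (opening → atrial activation onset, taken 2σ
  before the atrial Gaussian center) and AR (atrial onset → next closure);
  D/S is the ratio of the signed window volumes.
* Percent respiratory variation is 100·(max−min)/max of per-beat peaks
  across one respiratory cycle; for the transvalvular inflows the per-beat
  peak is the early-filling (E-wave) peak, taken while atrial activation
  is below 2 % — the atrium-driven A wave is insensitive to breathing and
  otherwise masks the modulation in the restrictive phenotypes.

## Limitations

* Gas exchange, airway mechanics, chemoreflexes, cerebral autoregulation,
  lymphatics and tissue water exchange are outside this model's scope; the
  coronary and cerebral beds are purely resistive shunts.
* The reflex reconstruction matches steady states only; transient reflex
  behavior is plausible but unverified.
* There is no atrioventricular-plane descent: atrial filling during
  ventricular systole is driven only by post-kick atrial relaxation, so
  the left-sided (pulmonary venous) systolic inflow fraction is
  underestimated — the model's control pulmonary venous D/S is ~1.4
  rather than the S-dominant ~0.7 seen clinically.  The right-sided
  (caval) D/S and its decline with LVDD severity are reproduced.
* The impaired-relaxation phenotype reaches the right heart only through
  septal and pericardial coupling, which leaves the IR tricuspid E/A near
  unity rather than clearly below it; the restrictive and pseudo-normal
  phenotypes show the expected tricuspid E/A < 1.
* Systemic veins have no collapse law; blood-volume reductions beyond
  ~5 % collapse the right atrium nonphysically.
* The synthetic fixture traces used to unit-test the extractors are
  piecewise-linear idealizations (triangular waves, rectangles); they
  validate the extraction arithmetic, not the physiology.
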