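# cardioloop

A closed-loop lumped-parameter model of the human cardiovascular system
for studying **left-ventricular diastolic dysfunction (LVDD)** and heart
failure with normal ejection fraction (HFNEF).  It is aimed at
computational physiologists and quantitative clinicians who want a
mechanistic sandbox in which a single diastolic parameter change (slowed
active relaxation, increased passive stiffness, or both) propagates
through a full circulation — septum, pericardium, pulmonary vasculature
and baroreflex included — and shows up in the same waveform indices an
echo lab would measure.

## The model

Four actively contracting chambers and an actively contracting
interventricular septum, each obeying an activation-weighted wall law

    P(V,t) = e(t)·α·E_ES·(V − V_d)  +  (1 − e(t))·P_0·(e^{λ(V−V_0)} − 1),

are wrapped in a common pericardium and embedded in closed systemic and
pulmonary networks of compliant compartments, resistive/inertial edges and
diode valves.  The septal volume satisfies a fixed point in the
trans-septal pressure P_SPT = P_LVF − P_RVF, solved by damped iteration at
every right-hand-side evaluation, so ventricular interdependence (septal
"priming" of RV ejection, pseudo-normalization masking) emerges from the
mechanics rather than being prescribed.  An arterial baroreflex (vagal and
sympathetic efferent limbs, first-order filtered) closes the loop on heart
rate, contractility α(F_con) and vasomotor tone.  The stiff beat-by-beat
dynamics are integrated with an adaptive Cash–Karp Runge–Kutta 4(5)
scheme compiled with numba.

Scenario engine: `CONTROL`, `IR` (impaired relaxation — widened terminal
activation Gaussian), `R` (restrictive — doubled λ of LV free wall and
septum), `PN` (both), `R_NSPT` (restrictive with a normal septum), each
optionally with 60 % augmented systolic contractility; fixed (−5 mmHg) or
breathing (−2…−6 mmHg, 7 s) pleural pressure.  From each steady-state run
the package extracts the clinical indices used to classify LVDD: E/A
ratio, E-wave deceleration time, IVRT, peak filling rate, filling
fractions, venous S/D/AR volumes, respiratory inflow variation, P-V loops
and stroke work.

See `docs/methods.md` for the full equations, parameter provenance and
limitations.

## Worked example

```python
from cardioloop import run_scenario

for dd in ("CONTROL", "PN"):
    traj, s, converged = run_scenario(dd)
    print(f"{dd}: HR {s.HR:.1f} bpm  CO {s.CO:.2f} l/min  LVEF {s.LVEF:.2f}  "
          f"RVEF {s.RVEF:.2f}  LVEDP {s.LVEDP:.1f} mmHg  "
          f"mitral E/A {s.mitral['E_A']:.2f}  DT {1e3*s.mitral['DT']:.0f} ms")
```

prints

```
CONTROL: HR 54.1 bpm  CO 4.94 l/min  LVEF 0.72  RVEF 0.58  LVEDP 9.6 mmHg  mitral E/A 1.06  DT 200 ms
PN: HR 66.4 bpm  CO 3.14 l/min  LVEF 0.66  RVEF 0.35  LVEDP 29.6 mmHg  mitral E/A 1.13  DT 132 ms
```

The pseudo-normal (PN) run is the HFNEF story in two lines: end-diastolic
pressure triples, cardiac output falls by more than a third, the right
ventricle is clearly depressed — yet the LV ejection fraction is 0.66 and
the mitral E/A ratio looks deceptively normal (1.13, vs 1.06 in control).
The giveaways are on the right side: the tricuspid E/A (0.72 here) does
not pseudo-normalize, and tricuspid inflow shows exaggerated respiratory
variation.

`traj` holds every pressure, volume and flow on a 1 ms grid
(`traj.to_frame()` gives a labeled DataFrame); `s` is the full
`HemodynamicSummary`.

The same runs are available from the shell:

```bash
cardioloop simulate --scenario PN --out-dir out/        # trajectory CSV + summary JSON
cardioloop table                                        # all 8 scenario columns, one CSV
cardioloop respiration                                  # breathing-variation report
```

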