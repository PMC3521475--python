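# Methods

## Model structure

The circulation is a closed loop of seven volume nodes: two actively
contracting ventricles (LV, RV) and five passive compliance compartments
(systemic arteries, systemic veins, right atrium, pulmonary arteries, and
a lumped pulmonary-veins/left-atrium node).  Seven resistors connect them
in a single series loop; the four valves (mitral, aortic, tricuspid,
pulmonary) are ideal diodes — forward flow `ΔP/R`, reverse flow exactly
zero.  Atria do not contract.  The right atrium, both ventricles, the
pulmonary arteries, and the left atrium are referenced to the
intrathoracic pressure; systemic arteries and veins are at ambient
pressure.  Respiration is a sinusoid on the intrathoracic pressure; blood
inertia is not modelled, so there is no dicrotic notch, and pulmonary
resistance is constant (not flow-dependent).

State: seven volumes, the low-pass MAoP monitor, the sympathetic drive
Sy, and a low-pass cardiac-output monitor (display only).  Volume is
conserved to floating-point accuracy because every flow leaves one node
and enters another.

### Ventricles

Time-varying elastance:

    P = a(φ) · E_ref · (g/100) · (1 + s·min(drive, 8)) · (V − V₀)
        + (V − V₀)/C_passive + ITP

* `φ` is the time since beat onset; systole lasts exactly 0.2 s at every
  heart rate (only diastole shortens with rate).
* `a(φ) = sin(π (φ/0.2)^k)` — a *skewed* half-sine (default `k = 1.58`)
  whose support is exactly the 0.2 s systole but whose peak sits near
  0.13 s rather than mid-systole.  The skew is what lets a weakly
  contracting ventricle reach its pressure maximum *late* in systole
  (>0.1 s) while the briskly ejecting normal ventricle peaks early
  (<0.1 s): with a symmetric half-sine the pressure maximum can never
  fall later than the activation peak, so the observed slow-contraction
  timing is unreachable.  `k = 1` recovers the symmetric shape
  (`activation_shape: half_sine`).
* Activation returns smoothly to zero at end-systole; the passive term
  `(V − V₀)/C_passive` is the diastolic P-V relation.  Because the
  chamber is referenced to the sub-atmospheric thorax, early-diastolic
  pressure of a well-emptied LV is slightly negative (~−2 mmHg at the
  default calibration).
* Contractility failure is `nominal_gain` 100 → 20 (an 80% cut of
  `E_max`); the inotropic limb can still raise the effective elastance
  through `(1 + s·min(Sy, 8))` up to the hard 8-FGU limiter.
* Severe aortic stenosis is an added series resistance at the LV output
  (`output_series_resistance`, 0.039 U in the builtin protocol).  With
  the model's ejection waveforms this value yields a ~50 mmHg sedentary
  and ~70 mmHg exercise gradient at preserved stroke volume — the
  hemodynamic signature of severe AVS (it also matches the linearised
  resistance of a ~0.7 cm² orifice at physiologic flow).

### Autonomic controller

A single drive signal Sy (FGU) follows first-order dynamics (lag
`sy_tau = 7.5 s`) toward `sy_baseline + G·(setpoint − MAoP_f)`, clipped to
[0, 8] FGU; `MAoP_f` is a 2.5 s first-order filter of aortic pressure and
`G = 0.13 FGU/mmHg`.  Three effector limbs, each with an on/off switch:

| limb | map | default |
|---|---|---|
| heart rate | `75 + 25·(Sy − 1)` 1/min, bounded [40, 124] | sampled once per beat, at onset |
| inotropy (LV and RV) | identity: drive = Sy, through the 8-FGU limiter | |
| venous tone | CVV reduction `330·(Sy − 1)` mL, saturating at ±520 mL | venoconstriction raises venous pressure |

The HR upper bound plays the role of the age-limited maximal heart rate;
it is what converts near-limiter sympathetic drive during exercise into
stroke-volume recruitment instead of runaway tachycardia.  The venous
saturation bounds how much volume venoconstriction can translocate
(an unbounded affine map would shift >1 L at high drive).  A limb whose
switch is turned off holds its last-on output; clamping `heart_rate` or
`sy` overrides the corresponding signal entirely — clamped Sy still
drives every enabled effector map.  The four reflex-syncope variants are
pure clamp settings: (a) 120/min, 1 FGU; (b) 120, 0.5; (c) 45, 0.5;
(d) 45, 1.5.

### Numerics

Fixed-step classical RK4 at `dt = 1 ms`.  Scenario events are
instantaneous parameter steps applied exactly on the grid; integration
restarts at each event.  Beats are scheduled by a discrete pacing clock:
at each onset the commanded HR is sampled and the next cycle length is
`round((60/HR)/dt)` steps, so traces are bitwise reproducible and beat
onsets can be reconstructed exactly from the recorded HR column.  There
is no random number generator anywhere in the package.  Integration
aborts with a diagnostic if any pressure leaves ±10⁴ mmHg or the state
becomes non-finite.  The fastest time constant of the default loop
(aortic valve × systolic LV elastance) is ≈3 ms, comfortably inside the
RK4 stability region at 1 ms.  The same kernel source runs either
numba-compiled (default) or as pure Python (`engine="python"`); a test
pins their agreement.

## Calibration (the frozen default parameter set)

The component values of the underlying analog-circuit family are not
available, so the defaults in `params/default.json` were calibrated once
against the reference per-phase hemodynamics and then frozen:

* The **operating point** is solved first with the controller clamped at
  its design values (Sy = 1 FGU, HR = 75/min): venous unstressed volume
  and LV elastance are adjusted until the baseline beat gives
  SV 87 mL and EF 63%, and the MAoP setpoint (102.1 mmHg) is then set to
  the plant's own mean aortic pressure at that point, so the closed-loop
  equilibrium coincides with the calibrated operating point.
* The remaining constants (feedback gain, actuator lag, HR map, venous
  tone slope and saturation, stenosis resistance, exercise setpoint reset
  of +44 mmHg) were tuned so that each later phase of the protocol
  reproduces its reference checkpoint set, and the four syncope variants
  their qualitative orderings.
* Resting cardiac output is ≈6.6 L/min at MAoP ≈103 mmHg with a total
  blood volume of ≈4.9 L — an unremarkable adult circulation.

Recalibration is a maintainer procedure (the scripts are not shipped);
the parameter file is the versioned artifact.

## Respiration and beat-to-beat variability

Respiration defaults: mean ITP −4 mmHg, amplitude 1 mmHg, period 4 s.
The 2 mmHg peak-to-peak swing (≈2.7 cmH₂O) corresponds to quiet
breathing.  Because the right heart is intrathoracic while the systemic
veins are not, venous return — and therefore stroke volume — is modulated
at the respiratory period by a few percent, exactly as in a real
circulation (at larger amplitudes the model shows a frank pulsus
paradoxus).  Steady state is therefore *periodic*, not constant:
steadiness is assessed by comparing beats one respiratory period apart
(same respiratory phase), which agree to <2% at the end of every protocol
phase, while consecutive beats may differ by the physiologic respiratory
swing.  Phase-window metrics are single-beat values at a deterministic
respiratory phase.

## Analysis conventions

* A cycle is the interval between consecutive pacing onsets; onset is
  end-diastole by construction, so EDV is the volume at onset and ESV the
  cycle minimum.  SV ≡ EDV − ESV and EF ≡ SV/EDV by definition.
* The transvalvular gradient is `max(LVP − AoP)` over samples where the
  aortic diode conducts (LVP > AoP), excluding spurious diastolic
  differences.
* Per-beat MAoP is the time average of AoP over the cycle (not the
  2·diastolic+systolic/3 estimator).
* Stroke work is the shoelace area of the closed P-V polygon; it matches
  an independent trapezoid integration of ∮P dV to <0.5%.
* Protocol phase windows (68.7–69.3 s, 103.7–104.3 s, 148.7–149.3 s,
  233.7–234.3 s, 543.7–544.3 s) are analysed as the full cycle containing
  the window midpoint.

## Known limitations

* No blood inertia (no dicrotic notch), no atrial contraction, no
  flow-dependent pulmonary resistance, no arteriolar-resistance feedback.
* The stenotic valve is a linear resistance; a real orifice is closer to
  quadratic (Gorlin), so gradients at flows far from the calibrated range
  are only indicative.
* Ejection is bounded by the fixed 0.2 s systole: with the stenosis in
  place, a bradycardic beat cannot eject more than the gradient-limited
  volume, so syncope variant (d) (HR 45, Sy 1.5) recovers cardiac output
  to only ~77% of baseline rather than "almost equal" — the model's
  flow-capped analogue of that observation; variant (a) recovers to
  within ~1%.
* The venous bed is a single linear compliance; orthostatic and regional
  pooling effects are out of scope.
* Elastances are linear in volume; the ESPVR has no curvature and no
  volume-axis intercept shift with inotropy.
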