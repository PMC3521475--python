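# cardioloop

A closed-loop, lumped-parameter (0-D) simulator of the human circulation,
built to study **exercise-induced reflex syncope in severe aortic valve
stenosis (AVS)**.  It is aimed at computational physiologists and
physiology educators who want a small, fully deterministic model in which
heart rate, ventricular contractility, and venous tone are governed by a
homeostatic negative-feedback controller that can be selectively disabled
— the defining experiment of reflex (neurally mediated) syncope.

## The model

The circulation is an eight-element closed hydraulic loop — left ventricle
(LV), systemic arteries, systemic veins, right atrium, right ventricle
(RV), pulmonary arteries, pulmonary veins/left atrium — in the electrical-
analog tradition (pressure ↔ voltage, flow ↔ current, volume ↔ charge,
1 U of flow resistance = 1 mmHg·s/mL ↔ 1 MΩ).  Passive compartments are
linear compliances, `P = (V − V₀)/C (+ ITP)`; the four heart valves are
ideal diodes (zero reverse flow); thoracic compartments are referenced to
a sinusoidal sub-atmospheric intrathoracic pressure (ITP).

Each ventricle is a time-varying elastance with a heart-rate-independent
systole of exactly 0.2 s:

    P(V, t) = a(t) · E_max,eff · (V − V₀) + (V − V₀)/C_passive + ITP
    E_max,eff = E_ref · (g/100) · (1 + s · min(Sy, 8))

where `a(t)` is a skewed half-sine supported on exactly [0, 0.2) s, `g` is
the nominal contractility gain (100 normal LV, ≈20 failing), and the
sympathetic drive `Sy` (in FGU, factor-of-gain units) feeds a limiter
that saturates at 8 FGU.

A single proportional controller with first-order lag regulates low-pass
filtered mean aortic pressure (MAoP) by driving three effector limbs —
heart rate, biventricular inotropy, and venoconstriction (reduction of the
venous unstressed volume, the "contractible volume of veins", CVV).  Each
limb has its own switch, and both controller outputs (HR, Sy) can be
clamped; that is how the four reflex-syncope variants are produced:
(a) HR 120/min, Sy 1 FGU; (b) 120, 0.5; (c) 45, 0.5; (d) 45, 1.5.

Integration is fixed-step RK4 (1 ms), restarted at every timed parameter
event, with a discrete pacing clock — runs are bitwise reproducible.

The builtin 550 s protocol walks one heart through five phases: normal →
failing LV (gain 100→20 at 70.5 s) → severe AVS (added outflow resistance
at 110.5 s) → exercise (peripheral resistance halved, MAoP setpoint raised
at 150.5 s) → reflex syncope (feedback clamped at 240.5 s).

## A worked example

```bash
python examples/stenosis_protocol.py
```

prints, from a single 550 s run (variant a):

```
phase                   EDV    ESV     SV   EF%   grad  maxLVP   MAoP    HR CO L/m
baseline              137.2   49.8   87.4  63.7   27.2   128.3  103.5  76.7   6.70
low_contractility     225.4  151.6   73.8  32.8   19.7   123.6   99.6  87.3   6.45
avs                   243.4  171.3   72.1  29.6   55.9   157.1   98.9  88.1   6.35
exercise              166.4   69.1   97.3  58.5   78.9   184.3  105.1 124.0  12.07
syncope               194.4  139.0   55.5  28.5   39.9    97.4   55.1 120.0   6.66
```

Reading the rows: the healthy heart ejects 87 mL per beat at an ejection
fraction of 64%.  When LV contractility fails, the ventricle dilates
(EDV 137→225 mL) and EF collapses to ~33%, but the feedback — tachycardia,
inotropy, venoconstriction — keeps cardiac output near 6.4 L/min.  The
stenosis adds a ~56 mmHg systolic gradient between LV and aorta (max LVP
157 mmHg); exercise raises the gradient to ~79 mmHg and max LVP to
184 mmHg while output doubles.  In the syncope row the feedback is gone:
with HR held at 120/min and Sy at 1 FGU, output is preserved (6.7 L/min)
but mean aortic pressure has fallen to 55 mmHg — hypotension with a
narrow pulse pressure, the classic vasodepressor picture.

Other examples: `run_baseline.py` (one healthy beat), `syncope_variants.py`
(all four failure modes side by side), `pv_loops.py` (P-V loops and stroke
work per phase), `custom_scenario.py` (user-defined YAML protocols).

A thin CLI wraps the same library:

```bash
cardioloop simulate --scenario paper_full_a --out run_a.csv
cardioloop analyze --in run_a.csv --window 148.7:149.3
cardioloop checkpoints          # all four variants + report
```

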