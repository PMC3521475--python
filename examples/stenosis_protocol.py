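"""The five-phase exertional-syncope protocol, phase by phase.

Runs the builtin 550 s protocol (variant a): normal heart, failing LV
(gain 100 -> 20), severe aortic valve stenosis, exercise, and finally
reflex syncope.  Prints the single-beat summary of each phase window —
watch the transvalvular gradient appear with the stenosis (~50 mmHg) and
grow with exercise (~70 mmHg) while the feedback keeps cardiac output up.
"""

from cardioloop import builtin_scenario, run
from cardioloop.beat import phase_metrics

result = run(builtin_scenario("paper_full_a"))

print(f"{'phase':20s} {'EDV':>6} {'ESV':>6} {'SV':>6} {'EF%':>5} "
      f"{'grad':>6} {'maxLVP':>7} {'MAoP':>6} {'HR':>5} {'CO L/m':>6}")
for phase, m in phase_metrics(result).items():
    print(f"{phase:20s} {m.EDVLV:6.1f} {m.ESVLV:6.1f} {m.SVLV:6.1f} "
          f"{m.EF * 100:5.1f} {m.peak_gradient:6.1f} {m.max_LVP:7.1f} "
          f"{m.MAoP:6.1f} {m.HR:5.1f} {m.CO / 1000:6.2f}")
print("\ngrad = peak systolic LVP - AoP while the aortic valve conducts;")
print("the syncope row is variant (a): HR clamped to 120/min, Sy to 1 FGU.")
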