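"""Simulate the healthy sedentary heart and summarise one cardiac cycle.

Runs the frozen default circulation for 70.5 s (the first ~50 s are
settle-in) and prints the per-beat hemodynamics of the cycle around 69 s:
stroke volume (~87 mL), ejection fraction (~63%), a slightly negative
early-diastolic LV pressure from the sub-atmospheric thorax, and mean
aortic pressure near the controller's setpoint.
"""

from cardioloop import builtin_scenario, run
from cardioloop.beat import beat_metrics, cycle_containing

result = run(builtin_scenario("baseline"))
cycle = cycle_containing(result, 68.7, 69.3)
m = beat_metrics(result, cycle)

print(f"cycle {cycle[0]:.3f}-{cycle[1]:.3f} s at HR {m.HR:.1f}/min")
print(f"  EDV {m.EDVLV:6.1f} mL   ESV {m.ESVLV:6.1f} mL   SV {m.SVLV:6.1f} mL")
print(f"  EF  {m.EF * 100:6.1f} %    CO {m.CO / 1000:5.2f} L/min")
print(f"  max LVP {m.max_LVP:6.1f} mmHg (peak at {m.time_to_peak_LVP * 1e3:.0f} ms)")
print(f"  min LVP {m.min_LVP:6.2f} mmHg  (early diastole, below atmospheric)")
print(f"  MAoP {m.MAoP:6.1f} mmHg   pulse pressure {m.pulse_pressure:5.1f} mmHg")
print(f"  stroke work {m.stroke_work:7.0f} mmHg*mL")
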