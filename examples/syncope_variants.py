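"""Compare the four reflex-syncope failure modes in steady state.

At 240.5 s the homeostatic feedback is replaced by fixed heart-rate and
sympathetic-drive (Sy) clamps.  By ~500 s each variant settles into a new
steady state; this prints the 543.7-544.3 s beat of each.  Expected
pattern: (a) preserved output despite hypotension, (b) everything lower,
(c) the deepest collapse (bradycardia + low drive), (d) near-baseline
output at low pressure with a very large pulse pressure.
"""

from cardioloop import builtin_scenario, run
from cardioloop.beat import beat_metrics, cycle_containing

rows = {}
for variant in "abcd":
    result = run(builtin_scenario(f"paper_full_{variant}"))
    rows[variant] = beat_metrics(result, cycle_containing(result, 543.7, 544.3))
    if variant == "a":
        baseline = beat_metrics(result, cycle_containing(result, 68.7, 69.3))

print(f"baseline reference: CO {baseline.CO / 1000:.2f} L/min, "
      f"MAoP {baseline.MAoP:.1f} mmHg, PP {baseline.pulse_pressure:.1f} mmHg\n")
print(f"{'variant':8s} {'HR':>5} {'Sy-clamp':>8} {'CO L/m':>7} {'dCO%':>6} "
      f"{'MAoP':>6} {'PP':>6} {'SV':>6}")
clamps = {"a": 1.0, "b": 0.5, "c": 0.5, "d": 1.5}
for v, m in rows.items():
    dco = (m.CO - baseline.CO) / baseline.CO * 100
    print(f"{v:8s} {m.HR:5.0f} {clamps[v]:8.1f} {m.CO / 1000:7.2f} {dco:+6.1f} "
          f"{m.MAoP:6.1f} {m.pulse_pressure:6.1f} {m.SVLV:6.1f}")
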