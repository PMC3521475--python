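"""Pressure-volume loops of the left ventricle across the protocol.

Extracts one P-V loop per phase of the five-phase protocol and prints the
loop's volume range and area (stroke work).  The loop shifts right as
contractility fails, further right and upward with the stenosis, then
left and upward in exercise.  If matplotlib is installed the loops are
also written to pv_loops.png.
"""

from cardioloop import builtin_scenario, run
from cardioloop.beat import loop_area, phase_metrics, pv_loop, cycle_containing
from cardioloop.scenario import PHASE_WINDOWS

result = run(builtin_scenario("paper_full_a"))

loops = {}
print(f"{'phase':20s} {'V range (mL)':>16} {'P range (mmHg)':>16} "
      f"{'stroke work':>12}")
for phase, (t0, t1) in PHASE_WINDOWS.items():
    loop = pv_loop(result, cycle_containing(result, t0, t1))
    loops[phase] = loop
    print(f"{phase:20s} {loop.volume.min():7.1f}-{loop.volume.max():6.1f} "
          f"{loop.pressure.min():8.1f}-{loop.pressure.max():6.1f} "
          f"{loop_area(loop):12.0f}")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for phase, loop in loops.items():
        ax.plot(loop.volume, loop.pressure, label=phase)
    ax.set_xlabel("LV volume (mL)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig("pv_loops.png", dpi=120)
    print("\nwrote pv_loops.png")
except ImportError:
    print("\n(matplotlib not installed; skipping the figure)")
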