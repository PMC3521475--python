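"""Tests for cycle segmentation, per-beat metrics, and P-V loop analysis."""

import numpy as np
import pandas as pd
import pytest

import cardioloop as cl
from cardioloop.beat import (BeatMetrics, PVLoop, beat_metrics,
                             checkpoint_report, cycle_boundaries,
                             cycle_containing, loop_area, pv_loop)
from cardioloop.errors import ConfigurationError
from cardioloop.model import SimulationResult


def _synthetic_result(lvv, lvp=None, aop=None, dt=0.01, hr=60.0):
    n = len(lvv)
    t = np.arange(n) * dt
    frame = pd.DataFrame({
        "t": t, "AoP": aop if aop is not None else np.full(n, 100.0),
        "MAoP": 100.0, "LVP": lvp if lvp is not None else np.zeros(n),
        "LAtP": 8.0, "CO": 5000.0, "CVV": 3000.0, "Sy": 1.0,
        "HR": hr, "LVV": lvv, "ITP": -4.0,
    })
    onsets = np.arange(0.0, t[-1], 60.0 / hr)
    return SimulationResult(frame=frame, beat_onsets=onsets, dt=dt)


# ---------------------------------------------------------------------------
# cycle boundaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hr, spacing", [(60.0, 1.0), (120.0, 0.5)])
def test_cycle_boundaries_spacing(hr, spacing):
    res = _synthetic_result(np.full(301, 100.0), hr=hr)
    cycles = cycle_boundaries(res)
    widths = {round(b - a, 9) for a, b in cycles}
    assert widths == {spacing}


def test_cycles_partition_the_pacing_span():
    res = _synthetic_result(np.full(301, 100.0), hr=60.0)
    cycles = cycle_boundaries(res)
    for (_, e1), (s2, _) in zip(cycles, cycles[1:]):
        assert e1 == s2
    assert cycles[0][0] == res.beat_onsets[0]
    assert cycles[-1][1] == res.beat_onsets[-1]


def test_empty_pacing_log_rejected():
    res = _synthetic_result(np.full(11, 100.0))
    with pytest.raises(ConfigurationError, match="empty"):
        cycle_boundaries(res, pacing_log=[])


# ---------------------------------------------------------------------------
# beat metrics
# ---------------------------------------------------------------------------

def test_beat_metrics_arithmetic_oracle():
    """EDV 138 at onset, minimum 51 -> SV 87, EF 63% (hand-computed)."""
    lvv = np.concatenate([
        np.linspace(138.0, 51.0, 40),   # ejection
        np.linspace(51.0, 138.0, 61),   # refill
    ])
    res = _synthetic_result(lvv, dt=0.01, hr=60.0)
    m = beat_metrics(res, (0.0, 1.0))
    assert m.EDVLV == 138.0 and m.ESVLV == 51.0
    assert m.SVLV == pytest.approx(87.0)
    assert m.EF == pytest.approx(87.0 / 138.0)
    assert m.CO == pytest.approx(87.0 * 60.0)


def test_constant_volume_gives_zero_stroke():
    res = _synthetic_result(np.full(301, 120.0))
    m = beat_metrics(res, (0.0, 1.0))
    assert m.SVLV == 0.0 and m.EF == 0.0


def test_sv_is_edv_minus_esv_on_simulated_beats(phase_beats):
    for m in phase_beats.values():
        assert m.SVLV == m.EDVLV - m.ESVLV  # identity, not measurement
        assert 0.0 <= m.EF <= 1.0


def test_peak_gradient_requires_forward_valve_pressure(phase_beats):
    for m in phase_beats.values():
        assert m.peak_gradient >= 0.0


def test_cycle_shorter_than_systole_rejected():
    res = _synthetic_result(np.full(301, 120.0))
    with pytest.raises(ConfigurationError):
        beat_metrics(res, (0.0, 0.1))


def test_ef_within_bounds_every_beat(full_run_a):
    for cyc in cycle_boundaries(full_run_a):
        m = beat_metrics(full_run_a, cyc)
        assert 0.0 <= m.EF <= 1.0


# ---------------------------------------------------------------------------
# P-V loops and stroke work
# ---------------------------------------------------------------------------

def test_pv_loop_is_closed(full_run_a):
    loop = pv_loop(full_run_a, cycle_containing(full_run_a, 68.7, 69.3))
    assert loop.volume[0] == loop.volume[-1]
    assert loop.pressure[0] == loop.pressure[-1]


def test_single_sample_cycle_rejected():
    res = _synthetic_result(np.full(301, 120.0))
    with pytest.raises(ConfigurationError):
        pv_loop(res, (0.0, 0.01))


def test_loop_area_rectangle():
    v = np.array([50.0, 100.0, 100.0, 50.0, 50.0])
    p = np.array([10.0, 10.0, 110.0, 110.0, 10.0])
    assert loop_area(PVLoop(v, p)) == pytest.approx(5000.0)


def test_loop_area_orientation_invariant():
    v = np.array([50.0, 100.0, 100.0, 50.0, 50.0])
    p = np.array([10.0, 10.0, 110.0, 110.0, 10.0])
    assert loop_area(PVLoop(v[::-1].copy(), p[::-1].copy())) == \
        pytest.approx(5000.0)


def test_loop_area_matches_independent_polygon_oracle():
    """Random convex polygons vs shapely's area computation."""
    from shapely.geometry import Polygon

    rng = np.random.default_rng(42)
    for _ in range(20):
        ang = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(5, 40)))
        r = rng.uniform(5.0, 50.0)
        v = 100.0 + r * np.cos(ang)
        p = 60.0 + r * np.sin(ang)
        v = np.append(v, v[0]); p = np.append(p, p[0])
        expected = Polygon(zip(v, p)).area
        assert loop_area(PVLoop(v, p)) == pytest.approx(expected, abs=1e-9)


def test_unclosed_loop_autocloses_with_warning():
    v = np.array([50.0, 100.0, 100.0, 50.0])
    p = np.array([10.0, 10.0, 110.0, 110.0])
    with pytest.warns(UserWarning, match="clos"):
        assert loop_area(PVLoop(v, p)) == pytest.approx(5000.0)


def test_stroke_work_equals_trapezoid_p_dv(full_run_a):
    """Shoelace stroke work vs an independent trapezoid integral of P dV."""
    cyc = cycle_containing(full_run_a, 68.7, 69.3)
    m = beat_metrics(full_run_a, cyc)
    f = full_run_a.frame
    seg = f[(f.t >= cyc[0]) & (f.t < cyc[1])]
    v = seg.LVV.to_numpy()
    p = seg.LVP.to_numpy()
    v = np.append(v, v[0]); p = np.append(p, p[0])
    integral = abs(np.sum(0.5 * (p[1:] + p[:-1]) * np.diff(v)))
    assert m.stroke_work == pytest.approx(integral, rel=0.005)


# ---------------------------------------------------------------------------
# loop shifts across protocol phases
# ---------------------------------------------------------------------------

def test_pv_loop_shifts_right_with_failing_contractility(full_run_a):
    base = pv_loop(full_run_a, cycle_containing(full_run_a, 68.7, 69.3))
    weak = pv_loop(full_run_a, cycle_containing(full_run_a, 103.7, 104.3))
    assert weak.volume.min() > base.volume.min()
    assert weak.volume.max() > base.volume.max()


def test_pv_loop_shifts_left_in_exercise_vs_stenosis(full_run_a):
    avs = pv_loop(full_run_a, cycle_containing(full_run_a, 148.7, 149.3))
    ex = pv_loop(full_run_a, cycle_containing(full_run_a, 233.7, 234.3))
    assert ex.volume.max() < avs.volume.max()
    assert ex.volume.min() < avs.volume.min()


def test_time_to_peak_slows_when_gain_drops(phase_beats):
    assert phase_beats["low_contractility"].time_to_peak_LVP > \
        phase_beats["baseline"].time_to_peak_LVP


# ---------------------------------------------------------------------------
# checkpoint report plumbing
# ---------------------------------------------------------------------------

def test_checkpoint_report_rejects_non_builtin_trace(full_run_a):
    with pytest.raises(ConfigurationError):
        checkpoint_report(full_run_a, "my_custom_protocol")


def test_checkpoint_report_rows(full_run_a):
    rep = checkpoint_report(full_run_a, "paper_full_a")
    assert set(rep.phase) >= {"baseline", "avs", "exercise"}
    assert {"SVLV", "EF%"} <= set(rep[rep.phase == "baseline"].metric)
    assert rep.within_tolerance.all()
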