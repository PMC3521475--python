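"""Per-beat hemodynamic summaries and pressure-volume loop diagnostics.

Cycles are defined by the simulator's pacing clock, not by threshold
detection: a beat onset is end-diastole by construction, so EDV is the
ventricular volume at onset and ESV the minimum over the cycle.  The
P-V loop of a cycle is the closed (volume, pressure) trajectory; its
shoelace area is the stroke work in mmHg·mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import SimulationResult

__all__ = [
    "BeatMetrics",
    "PVLoop",
    "cycle_boundaries",
    "beat_metrics",
    "cycle_containing",
    "pv_loop",
    "loop_area",
    "checkpoint_report",
    "CHECKPOINTS",
]


@dataclass
class BeatMetrics:
    """Summary of one cardiac cycle of the left ventricle."""

    t_onset: float  # s
    EDVLV: float  # mL
    ESVLV: float  # mL
    SVLV: float  # mL, = EDVLV - ESVLV
    EF: float  # fraction, SVLV / EDVLV
    EDPLV: float  # mmHg, LVP at onset
    max_LVP: float  # mmHg
    time_to_peak_LVP: float  # s from onset
    min_LVP: float  # mmHg (diastolic dip; negative with thoracic reference)
    peak_gradient: float  # mmHg, max systolic LVP - AoP while ejecting
    MAoP: float  # mmHg, time-average AoP over the cycle
    pulse_pressure: float  # mmHg
    CO: float  # mL/min, SVLV * HR
    HR: float  # 1/min
    stroke_work: float  # mmHg*mL


@dataclass
class PVLoop:
    """Closed (volume, pressure) trajectory of one cycle."""

    volume: np.ndarray  # mL
    pressure: np.ndarray  # mmHg

    def __post_init__(self) -> None:
        if self.volume.shape != self.pressure.shape:
            raise ConfigurationError("PVLoop: volume/pressure length mismatch")


def cycle_boundaries(trace: SimulationResult | pd.DataFrame,
                     pacing_log: Optional[Sequence[float]] = None
                     ) -> list[tuple[float, float]]:
    """Half-open, contiguous per-beat intervals ``[t_onset_i, t_onset_i+1)``.

    ``pacing_log`` defaults to the simulator's recorded beat onsets.
    """
    if pacing_log is None:
        if not isinstance(trace, SimulationResult):
            raise ConfigurationError(
                "cycle_boundaries: a pacing log is required for raw frames"
            )
        pacing_log = trace.beat_onsets
    onsets = np.asarray(pacing_log, dtype=float)
    if onsets.size == 0:
        raise ConfigurationError("cycle_boundaries: empty pacing log")
    frame = trace.frame if isinstance(trace, SimulationResult) else trace
    t = frame["t"].to_numpy()
    if onsets[0] < t[0] - 1e-9 or onsets[-1] > t[-1] + 1e-9:
        raise ConfigurationError("pacing log extends beyond the trace span")
    return [(float(a), float(b)) for a, b in zip(onsets[:-1], onsets[1:])]


def _slice(frame: pd.DataFrame, cycle: tuple[float, float]) -> pd.DataFrame:
    t = frame["t"].to_numpy()
    i0 = int(np.searchsorted(t, cycle[0] - 1e-9))
    i1 = int(np.searchsorted(t, cycle[1] - 1e-9))
    return frame.iloc[i0:i1]


def beat_metrics(trace: SimulationResult | pd.DataFrame,
                 cycle: tuple[float, float]) -> BeatMetrics:
    """Compute the per-beat summary for one pacing cycle."""
    frame = trace.frame if isinstance(trace, SimulationResult) else trace
    seg = _slice(frame, cycle)
    if len(seg) < 3:
        raise ConfigurationError(
            f"cycle {cycle} holds {len(seg)} samples; too short to analyse"
        )
    lvv = seg["LVV"].to_numpy()
    lvp = seg["LVP"].to_numpy()
    aop = seg["AoP"].to_numpy()
    t = seg["t"].to_numpy()
    hr = float(seg["HR"].iloc[0])
    span = cycle[1] - cycle[0]
    if span < 0.2:
        raise ConfigurationError(
            f"cycle {cycle} is shorter than one systole"
        )
    edv = float(lvv[0])
    esv = float(lvv.min())
    sv = edv - esv
    grad = lvp - aop
    ejecting = grad > 0.0  # the aortic diode conducts iff LVP > AoP
    peak_gradient = float(grad[ejecting].max()) if ejecting.any() else 0.0
    ipk = int(np.argmax(lvp))
    return BeatMetrics(
        t_onset=float(t[0]),
        EDVLV=edv,
        ESVLV=esv,
        SVLV=sv,
        EF=sv / edv if edv > 0 else 0.0,
        EDPLV=float(lvp[0]),
        max_LVP=float(lvp.max()),
        time_to_peak_LVP=float(t[ipk] - t[0]),
        min_LVP=float(lvp.min()),
        peak_gradient=peak_gradient,
        MAoP=float(aop.mean()),
        pulse_pressure=float(aop.max() - aop.min()),
        CO=sv * hr,
        HR=hr,
        stroke_work=loop_area(pv_loop(trace, cycle)),
    )


def cycle_containing(result: SimulationResult, t0: float, t1: float
                     ) -> tuple[float, float]:
    """The pacing cycle containing the midpoint of the window [t0, t1]."""
    mid = 0.5 * (t0 + t1)
    for cycle in cycle_boundaries(result):
        if cycle[0] <= mid < cycle[1]:
            return cycle
    raise ConfigurationError(f"no cycle contains t={mid:.3f} s")


def pv_loop(trace: SimulationResult | pd.DataFrame,
            cycle: tuple[float, float]) -> PVLoop:
    """P-V trajectory of one cycle, closed by appending the first point."""
    frame = trace.frame if isinstance(trace, SimulationResult) else trace
    seg = _slice(frame, cycle)
    if len(seg) < 2:
        raise ConfigurationError(f"cycle {cycle} too short for a P-V loop")
    v = seg["LVV"].to_numpy()
    p = seg["LVP"].to_numpy()
    return PVLoop(volume=np.append(v, v[0]), pressure=np.append(p, p[0]))


def loop_area(loop: PVLoop) -> float:
    """Stroke work: absolute shoelace area of the closed P-V polygon."""
    v, p = loop.volume, loop.pressure
    if v.size < 3:
        raise ConfigurationError("loop_area: need at least 3 points")
    if v[0] != v[-1] or p[0] != p[-1]:
        warnings.warn("loop_area: unclosed loop; closing it", stacklevel=2)
        v = np.append(v, v[0])
        p = np.append(p, p[0])
    return float(abs(np.sum(v[:-1] * p[1:] - v[1:] * p[:-1])) / 2.0)


# ---------------------------------------------------------------------------
# checkpoint report
# ---------------------------------------------------------------------------
# Reference hemodynamic checkpoints of the five-phase protocol, one row per
# quantity: (id, phase, metric, reference value, comparison, tolerance).
# "eq": |sim - ref| <= tol; "le": ref - tol <= sim <= ref.
CHECKPOINTS = (
    ("t1", "baseline", "SVLV", 87.0, "eq", 87.0 * 0.05),
    ("t2", "baseline", "EF%", 63.0, "eq", 3.0),
    ("t3", "low_contractility", "EF%", 30.0, "eq", 5.0),
    ("t4", "avs", "peak_gradient", 50.0, "eq", 10.0),
    ("t5", "avs", "max_LVP", 170.0, "le", 15.0),
    ("t6", "avs", "EF%", 25.0, "eq", 5.0),
    ("t7", "exercise", "peak_gradient", 70.0, "eq", 10.0),
    ("t8", "exercise", "max_LVP", 190.0, "le", 15.0),
    ("t9", "exercise", "SVLV", 107.0, "eq", 10.7),
    ("t10", "exercise", "EF%", 56.0, "eq", 5.0),
    ("t11", "structural", "systole_width", 0.2, "eq", 0.001),
)


def _metric_value(m: BeatMetrics, metric: str) -> float:
    if metric == "EF%":
        return m.EF * 100.0
    return getattr(m, metric)


def phase_metrics(result: SimulationResult) -> dict[str, BeatMetrics]:
    """Beat metrics for each protocol phase window present in the trace."""
    from .scenario import PHASE_WINDOWS

    out = {}
    for phase, (t0, t1) in PHASE_WINDOWS.items():
        if t1 <= result.duration + 1e-9:
            out[phase] = beat_metrics(result, cycle_containing(result, t0, t1))
    return out


def systole_width(hr: float, dt: float = 0.001,
                  params=None) -> float:
    """Measured activation-support width (s) at a clamped heart rate.

    Runs a short simulation with heart rate clamped to ``hr`` and measures
    the width of the per-cycle interval where ventricular activation is
    positive.  Activation is positive on an open interval sampled strictly
    inside, so the support measure is ``(n_positive + 1) * dt``.
    """
    import copy

    from . import io as _io
    from . import model

    network, control = params if params is not None else _io.load_params()
    network = copy.deepcopy(network)
    control = copy.deepcopy(control)
    control.clamps["heart_rate"] = hr
    res = model.integrate(network, control, (0.0, 6.0), dt=dt)
    # reconstruct per-sample activation from the pacing log
    lv = network.ventricles["lv"]
    onsets = res.beat_onsets
    widths = []
    for a, b in zip(onsets[1:-1], onsets[2:]):  # interior, complete beats
        n = int(round((b - a) / dt))
        phases = np.arange(n) * dt
        from .model import ventricular_activation

        act = np.array([
            ventricular_activation(ph, lv.systole_duration,
                                   lv.activation_shape,
                                   lv.diastolic_relaxation_tau,
                                   lv.activation_skew)
            for ph in phases
        ])
        widths.append((int((act > 0).sum()) + 1) * dt)
    widths = sorted(set(round(w, 9) for w in widths))
    if len(widths) != 1:
        raise ConfigurationError(
            f"activation support varies across beats at HR {hr}: {widths}"
        )
    return widths[0]


def checkpoint_report(result: SimulationResult, scenario_name: str,
                      params=None) -> pd.DataFrame:
    """Evaluate every reference checkpoint against a builtin protocol run.

    Returns a table with one row per checkpoint: the simulated value, the
    reference value, and whether it lies within tolerance.  Only traces
    produced by the builtin ``paper_full_*`` scenarios are accepted (the
    phase windows are protocol-defined).
    """
    from .scenario import BUILTIN_NAMES

    if scenario_name not in BUILTIN_NAMES or scenario_name == "baseline":
        raise ConfigurationError(
            f"checkpoint_report needs a paper_full_* scenario trace "
            f"(got {scenario_name!r})"
        )
    missing = [c for c in ("LVV", "LVP", "AoP", "HR") if c not in result.frame]
    if missing:
        raise ConfigurationError(f"trace lacks variables: {missing}")
    metrics = phase_metrics(result)
    rows = []
    for cid, phase, metric, ref, cmp_kind, tol in CHECKPOINTS:
        if phase == "structural":
            widths = [systole_width(h, result.dt, params) for h in (45.0, 60.0, 120.0)]
            sim = widths[0]
            ok = len(set(widths)) == 1 and abs(sim - ref) <= tol
        else:
            sim = _metric_value(metrics[phase], metric)
            if cmp_kind == "le":
                ok = (ref - tol) <= sim <= ref
            else:
                ok = abs(sim - ref) <= tol
        rows.append({
            "id": cid, "phase": phase, "metric": metric,
            "simulated": round(float(sim), 4), "reference": ref,
            "cmp": cmp_kind, "tolerance": tol, "within_tolerance": bool(ok),
        })
    return pd.DataFrame(rows)
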