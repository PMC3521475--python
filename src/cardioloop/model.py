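"""Closed-loop hydraulic model: constitutive laws and time integration.

The network of :mod:`cardioloop.network` is translated into a compartmental
mass balance (one ODE per chamber volume) plus three controller states
(filtered MAoP, the sympathetic drive Sy, and a low-passed cardiac-output
monitor).  Integration is fixed-step classical RK4, restarted at every
scenario event, so runs are deterministic and output files are bitwise
reproducible.

The heart is paced by a discrete clock: beat onsets are scheduled one
cycle length (``60/HR``, rounded to the integration grid) apart, with the
heart rate sampled once per beat at its onset.  The activation waveform of
both ventricles is a (skewed) half-sine whose support is exactly the
(heart-rate independent) systole duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import control as ctl
from .errors import ConfigurationError, IntegrationError
from .network import NetworkSpec, RespirationSpec, HemoState
from .units import MLS_TO_MLMIN

__all__ = [
    "COLUMNS",
    "SimulationResult",
    "valve_flow",
    "ventricular_activation",
    "effective_gain",
    "ventricular_pressure",
    "intrathoracic_pressure",
    "node_pressures",
    "flows",
    "derivatives",
    "integrate",
    "integrate_passive",
]

#: Fixed column order of every time-series table and CSV file.
COLUMNS = ("t", "AoP", "MAoP", "LVP", "LAtP", "CO", "CVV", "Sy", "HR", "LVV", "ITP")

#: Abort threshold: any pressure beyond this is numerical blow-up.
PRESSURE_LIMIT = 1.0e4  # mmHg

#: Floor for the effective venous unstressed volume under venoconstriction.
MIN_VENOUS_UNSTRESSED = 50.0  # mL


# ---------------------------------------------------------------------------
# elementary constitutive laws (public operations)
# ---------------------------------------------------------------------------

def valve_flow(p_upstream: float, p_downstream: float, resistance: float,
               one_way: bool) -> float:
    """Flow (mL/s) through a resistor, optionally a valve (ideal diode).

    Forward flow follows the hydraulic Ohm analogue ``(Pup - Pdown) / R``;
    a one-way element carries exactly zero reverse flow.
    """
    if resistance <= 0:
        raise ConfigurationError(
            f"valve_flow: resistance must be > 0 (got {resistance})"
        )
    dp = p_upstream - p_downstream
    if one_way and dp <= 0.0:
        return 0.0
    return dp / resistance


def ventricular_activation(phase: float, systole_duration: float = 0.2,
                           shape: str = "skewed_half_sine",
                           relaxation_tau: float = 0.05,
                           skew: float = 1.45) -> float:
    """Normalized activation ``a(phase)`` in [0, 1].

    ``half_sine`` is the symmetric wave ``sin(pi * phase/Ts)``;
    ``skewed_half_sine`` (the default) warps the time axis,
    ``sin(pi * (phase/Ts)**skew)``, placing the activation peak past
    mid-systole for ``skew > 1`` — a weakly contracting ventricle then
    reaches its pressure maximum late in systole, as observed.  Either
    way the support of ``a > 0`` is exactly ``systole_duration`` at any
    heart rate, and activation falls smoothly to zero at end-systole; any
    residual end-systolic activation (identically zero for these shapes)
    would decay exponentially with ``relaxation_tau``.
    """
    if shape not in ("half_sine", "skewed_half_sine"):
        raise ConfigurationError(f"unknown activation shape {shape!r}")
    if phase < 0.0:
        return 0.0
    u = phase / systole_duration
    if u < 1.0:
        if shape == "half_sine":
            return math.sin(math.pi * u)
        return math.sin(math.pi * u ** skew)
    a_end = 0.0  # both shapes vanish at end-systole
    if a_end == 0.0:
        return 0.0
    return a_end * math.exp(-(phase - systole_duration) / relaxation_tau)


def effective_gain(nominal_gain: float, inotropic_drive: float,
                   limiter_max: float = 8.0, slope: float = 0.5) -> float:
    """Contractility gain after the inotropic effector and its limiter.

    ``g_eff = nominal_gain * (1 + slope * min(drive, limiter_max))`` —
    monotone, non-decreasing in the drive, saturating exactly at
    ``limiter_max`` FGU.  Zero drive returns the nominal gain unchanged.
    Negative drive is clipped to zero.
    """
    if inotropic_drive < 0:
        import warnings

        warnings.warn(
            f"negative inotropic drive ({inotropic_drive} FGU) clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        inotropic_drive = 0.0
    return nominal_gain * (1.0 + slope * min(inotropic_drive, limiter_max))


def ventricular_pressure(volume: float, activation: float, e_max_eff: float,
                         unstressed_volume: float, passive_compliance: float,
                         itp: float = 0.0) -> float:
    """Chamber pressure of a time-varying-elastance ventricle (mmHg).

    ``P = a * E_max_eff * (V - V0) + (V - V0)/C_passive + ITP``.  With the
    sub-atmospheric intrathoracic reference the diastolic pressure of a
    well-emptied ventricle is slightly negative.
    """
    if volume < 0:
        raise ConfigurationError(f"ventricular volume must be >= 0 (got {volume})")
    dv = volume - unstressed_volume
    return activation * e_max_eff * dv + dv / passive_compliance + itp


def intrathoracic_pressure(t: float, resp: RespirationSpec) -> float:
    """Sinusoidal intrathoracic pressure (mmHg) at time ``t``."""
    if resp.amplitude == 0.0:
        return resp.mean_itp
    return resp.mean_itp + resp.amplitude * math.sin(2.0 * math.pi * t / resp.period)


# ---------------------------------------------------------------------------
# generic (any-topology) mass balance — reference path and test oracle
# ---------------------------------------------------------------------------

def node_pressures(state: HemoState, network: NetworkSpec,
                   effectors: Optional[ctl.EffectorOutputs] = None,
                   t: Optional[float] = None) -> dict[str, float]:
    """Absolute pressure (mmHg) of every compartment and ventricle."""
    if t is None:
        t = state.t
    itp = intrathoracic_pressure(t, network.respiration)
    pressures: dict[str, float] = {}
    for c in network.compartments:
        v0 = c.unstressed_volume
        if effectors is not None and c.name == "systemic_veins":
            v0 = max(v0 - effectors.venous_unstressed_delta, MIN_VENOUS_UNSTRESSED)
        p = (state.volumes[c.name] - v0) / c.compliance
        if c.external_pressure_source == "intrathoracic":
            p += itp
        pressures[c.name] = p
    for name, vent in (network.ventricles or {}).items():
        drive = 0.0
        if effectors is not None:
            drive = effectors.lv_drive if name == "lv" else effectors.rv_drive
        g = effective_gain(vent.nominal_gain, max(drive, 0.0),
                           vent.limiter_max, vent.inotropic_slope)
        e_max = vent.e_max_ref * g / 100.0
        a = ventricular_activation(state.cardiac_phase, vent.systole_duration,
                                   vent.activation_shape,
                                   vent.diastolic_relaxation_tau,
                                   vent.activation_skew)
        p_ext = itp if vent.external_pressure_source == "intrathoracic" else 0.0
        pressures[name] = ventricular_pressure(
            state.volumes[name], a, e_max, vent.unstressed_volume,
            vent.passive_compliance, p_ext)
    return pressures


def flows(state: HemoState, network: NetworkSpec,
          effectors: Optional[ctl.EffectorOutputs] = None,
          t: Optional[float] = None) -> dict[str, float]:
    """Flow (mL/s) through every resistor; one-way elements never reverse."""
    pressures = node_pressures(state, network, effectors, t)
    out: dict[str, float] = {}
    for r in network.resistors:
        resistance = r.resistance
        if network.ventricles and r.upstream in network.ventricles:
            resistance += network.ventricles[r.upstream].output_series_resistance
        q = valve_flow(pressures[r.upstream], pressures[r.downstream],
                       resistance, r.one_way)
        if not math.isfinite(q):
            raise IntegrationError(
                f"non-finite flow through resistor {r.name!r} at t={t}"
            )
        out[r.name] = q
    return out


def derivatives(state: HemoState, network: NetworkSpec,
                effectors: Optional[ctl.EffectorOutputs] = None,
                t: Optional[float] = None) -> dict[str, float]:
    """Volume derivatives dV/dt (mL/s) for every node of ``network``.

    Mass balance over the resistor graph: each flow leaves its upstream
    node and enters its downstream node, so the derivatives sum to zero
    (closed loop).  Works for arbitrary topologies, including passive
    test networks without ventricles.
    """
    q = flows(state, network, effectors, t)
    dv = {name: 0.0 for name in state.volumes}
    for r in network.resistors:
        dv[r.upstream] -= q[r.name]
        dv[r.downstream] += q[r.name]
    return dv


def integrate_passive(network: NetworkSpec, t_span: tuple[float, float],
                      dt: float = 0.001) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Fixed-step RK4 on a passive (ventricle-less) network.

    A small reference integrator for component-level studies such as the
    RC-discharge relaxation of an isolated compartment pair.  Returns the
    sampled times and per-compartment volume traces.
    """
    if network.ventricles:
        raise ConfigurationError("integrate_passive handles passive networks only")
    if dt <= 0 or t_span[1] <= t_span[0]:
        raise ConfigurationError("integrate_passive: need dt > 0 and t1 > t0")
    names = [c.name for c in network.compartments]
    n = int(round((t_span[1] - t_span[0]) / dt))
    out = {name: np.empty(n + 1) for name in names}
    vols = {c.name: c.initial_volume for c in network.compartments}

    def f(v, t):
        st = HemoState(t=t, volumes=v, cardiac_phase=1e9, sy=0.0, heart_rate=60.0)
        return derivatives(st, network, None, t)

    for i in range(n + 1):
        t = t_span[0] + i * dt
        for name in names:
            out[name][i] = vols[name]
        if i == n:
            break
        k1 = f(vols, t)
        k2 = f({m: vols[m] + 0.5 * dt * k1[m] for m in names}, t + 0.5 * dt)
        k3 = f({m: vols[m] + 0.5 * dt * k2[m] for m in names}, t + 0.5 * dt)
        k4 = f({m: vols[m] + dt * k3[m] for m in names}, t + dt)
        vols = {
            m: vols[m] + dt / 6.0 * (k1[m] + 2 * k2[m] + 2 * k3[m] + k4[m])
            for m in names
        }
    times = t_span[0] + dt * np.arange(n + 1)
    return times, out


# ---------------------------------------------------------------------------
# compiled closed-loop kernel (single source, optionally numba-jitted)
# ---------------------------------------------------------------------------
# State vector x (10): [V_lv, V_sa, V_sv, V_ra, V_rv, V_pa, V_la,
#                       MAoP_filter, Sy, CO_filter]
# Parameter vector p: see _pack() for the layout.

_NP = 62  # length of the parameter vector


def _make_kernels(jit: bool):
    if jit:
        from numba import njit

        deco = njit(cache=False)
    else:
        def deco(f):
            return f

    pi = math.pi

    @deco
    def deriv(x, p, phase, t, dx, aux):
        itp = p[33] + p[34] * math.sin(2.0 * pi * t / p[35])
        # effective (possibly clamped) drive signal
        sy_eff = p[54] if p[54] >= 0.0 else x[8]
        lv_drive = sy_eff if p[50] == 1.0 else p[56]
        rv_drive = sy_eff if p[51] == 1.0 else p[57]
        if p[52] == 1.0:
            ven_delta = p[47] * (sy_eff - p[39])
            if ven_delta > p[61]:
                ven_delta = p[61]
            elif ven_delta < -p[61]:
                ven_delta = -p[61]
        else:
            ven_delta = p[58]
        if lv_drive < 0.0:
            lv_drive = 0.0
        if rv_drive < 0.0:
            rv_drive = 0.0
        v0_sv = p[6] - ven_delta
        if v0_sv < 50.0:
            v0_sv = 50.0

        # ventricular activation (shared pacing clock, skewed half-sine)
        if 0.0 <= phase < p[23]:
            a_lv = math.sin(pi * (phase / p[23]) ** p[59])
        else:
            a_lv = 0.0
        if 0.0 <= phase < p[31]:
            a_rv = math.sin(pi * (phase / p[31]) ** p[60])
        else:
            a_rv = 0.0

        d = lv_drive if lv_drive < p[22] else p[22]
        e_lv = p[19] * (p[20] / 100.0) * (1.0 + p[21] * d)
        d = rv_drive if rv_drive < p[30] else p[30]
        e_rv = p[27] * (p[28] / 100.0) * (1.0 + p[29] * d)

        # pressures
        dv_lv = x[0] - p[17]
        p_lv = a_lv * e_lv * dv_lv + dv_lv / p[18] + itp
        dv_rv = x[4] - p[25]
        p_rv = a_rv * e_rv * dv_rv + dv_rv / p[26] + itp
        p_sa = (x[1] - p[5]) / p[0]
        p_sv = (x[2] - v0_sv) / p[1]
        p_ra = (x[3] - p[7]) / p[2] + itp
        p_pa = (x[5] - p[8]) / p[3] + itp
        p_la = (x[6] - p[9]) / p[4] + itp

        # flows (valves are ideal diodes: zero reverse flow)
        q_av = (p_lv - p_sa) / p[10] if p_lv > p_sa else 0.0
        q_sys = (p_sa - p_sv) / p[11]
        q_ven = (p_sv - p_ra) / p[12]
        q_tri = (p_ra - p_rv) / p[13] if p_ra > p_rv else 0.0
        q_pv = (p_rv - p_pa) / p[14] if p_rv > p_pa else 0.0
        q_pul = (p_pa - p_la) / p[15]
        q_mit = (p_la - p_lv) / p[16] if p_la > p_lv else 0.0

        dx[0] = q_mit - q_av
        dx[1] = q_av - q_sys
        dx[2] = q_sys - q_ven
        dx[3] = q_ven - q_tri
        dx[4] = q_tri - q_pv
        dx[5] = q_pv - q_pul
        dx[6] = q_pul - q_mit

        # controller states
        dx[7] = (p_sa - x[7]) / p[37]
        if p[54] >= 0.0:
            dx[8] = 0.0
        else:
            tgt = p[39] + p[38] * (p[36] - x[7])
            if tgt < p[40]:
                tgt = p[40]
            elif tgt > p[41]:
                tgt = p[41]
            dx[8] = (tgt - x[8]) / p[42]
        dx[9] = (q_av * 60.0 - x[9]) / p[48]

        aux[0] = p_sa
        aux[1] = p_lv
        aux[2] = p_la
        aux[3] = itp
        aux[4] = v0_sv
        aux[5] = sy_eff

    @deco
    def run_segment(x, p, out, row0, step0, n_steps, dt,
                    steps_into_beat, period_steps, hr_current,
                    beat_times, n_beats):
        k1 = np.empty(10)
        k2 = np.empty(10)
        k3 = np.empty(10)
        k4 = np.empty(10)
        xt = np.empty(10)
        aux = np.empty(6)
        aux2 = np.empty(6)
        for i in range(n_steps):
            t = (step0 + i) * dt
            if steps_into_beat >= period_steps:
                # new beat: sample the commanded heart rate once, at onset
                steps_into_beat = 0
                if p[53] >= 0.0:
                    hr = p[53]
                else:
                    sy_eff = p[54] if p[54] >= 0.0 else x[8]
                    if p[49] == 1.0:
                        hr = p[43] + p[44] * (sy_eff - p[39])
                        if hr < p[45]:
                            hr = p[45]
                        elif hr > p[46]:
                            hr = p[46]
                    else:
                        hr = p[55]
                if not (1.0 <= hr <= 1000.0):  # guards NaN states too
                    hr = 60.0
                period_steps = int(round(60.0 / (hr * dt)))
                if period_steps < 1:
                    period_steps = 1
                hr_current = 60.0 / (period_steps * dt)
                if n_beats < beat_times.shape[0]:
                    beat_times[n_beats] = t
                    n_beats += 1

            phase = steps_into_beat * dt
            deriv(x, p, phase, t, k1, aux)

            r = row0 + i
            out[r, 0] = t
            out[r, 1] = aux[0]
            out[r, 2] = x[7]
            out[r, 3] = aux[1]
            out[r, 4] = aux[2]
            out[r, 5] = x[9]
            out[r, 6] = aux[4]
            out[r, 7] = aux[5]
            out[r, 8] = hr_current
            out[r, 9] = x[0]
            out[r, 10] = aux[3]

            h2 = 0.5 * dt
            for j in range(10):
                xt[j] = x[j] + h2 * k1[j]
            deriv(xt, p, phase + h2, t + h2, k2, aux2)
            for j in range(10):
                xt[j] = x[j] + h2 * k2[j]
            deriv(xt, p, phase + h2, t + h2, k3, aux2)
            for j in range(10):
                xt[j] = x[j] + dt * k3[j]
            deriv(xt, p, phase + dt, t + dt, k4, aux2)
            h6 = dt / 6.0
            for j in range(10):
                x[j] += h6 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            # saturate Sy inside its admissible range
            if x[8] < p[40]:
                x[8] = p[40]
            elif x[8] > p[41]:
                x[8] = p[41]
            steps_into_beat += 1
            # abort on numerical blow-up: mark and stop integrating
            if not (abs(x[0]) < 1.0e9) or not (x[8] == x[8]):
                for rr in range(r + 1, row0 + n_steps):
                    out[rr, 0] = (step0 + rr - row0) * dt
                    for cc in range(1, 11):
                        out[rr, cc] = np.nan
                break
        return steps_into_beat, period_steps, hr_current, n_beats

    return deriv, run_segment


_deriv_py, _run_py = _make_kernels(jit=False)
try:  # pragma: no cover - exercised implicitly by default runs
    _deriv_nb, _run_nb = _make_kernels(jit=True)
except ImportError:  # pragma: no cover
    _deriv_nb, _run_nb = _deriv_py, _run_py


def _pack(network: NetworkSpec, control: ctl.ControlSpec,
          frozen: ctl.EffectorOutputs) -> np.ndarray:
    """Flatten specs into the kernel parameter vector."""
    p = np.zeros(_NP)
    comp = {c.name: c for c in network.compartments}
    order = ("systemic_arteries", "systemic_veins", "right_atrium",
             "pulmonary_arteries", "left_atrium")
    for i, name in enumerate(order):
        p[i] = comp[name].compliance
        p[5 + i] = comp[name].unstressed_volume
    res = {r.name: r for r in network.resistors}
    lv = network.ventricles["lv"]
    rv = network.ventricles["rv"]
    p[10] = res["aortic_valve"].resistance + lv.output_series_resistance
    p[11] = res["systemic_peripheral"].resistance
    p[12] = res["venous_return"].resistance
    p[13] = res["tricuspid_valve"].resistance
    p[14] = res["pulmonary_valve"].resistance + rv.output_series_resistance
    p[15] = res["pulmonary_peripheral"].resistance
    p[16] = res["mitral_valve"].resistance
    for base, v in ((17, lv), (25, rv)):
        p[base + 0] = v.unstressed_volume
        p[base + 1] = v.passive_compliance
        p[base + 2] = v.e_max_ref
        p[base + 3] = v.nominal_gain
        p[base + 4] = v.inotropic_slope
        p[base + 5] = v.limiter_max
        p[base + 6] = v.systole_duration
        p[base + 7] = v.diastolic_relaxation_tau
    p[33] = network.respiration.mean_itp
    p[34] = network.respiration.amplitude
    p[35] = network.respiration.period
    p[36] = control.maop_setpoint
    p[37] = control.maop_filter_tau
    p[38] = control.feedback_gain
    p[39] = control.sy_baseline
    p[40], p[41] = control.sy_range
    p[42] = control.sy_tau
    p[43] = control.hr_base
    p[44] = control.hr_per_fgu
    p[45], p[46] = control.hr_bounds
    p[47] = control.venous_ml_per_fgu
    p[48] = control.co_filter_tau
    p[49] = 1.0 if control.switches.get("hr", True) else 0.0
    p[50] = 1.0 if control.switches.get("lv_inotropy", True) else 0.0
    p[51] = 1.0 if control.switches.get("rv_inotropy", True) else 0.0
    p[52] = 1.0 if control.switches.get("venous_tone", True) else 0.0
    p[53] = control.clamps.get("heart_rate", -1.0)
    p[54] = control.clamps.get("sy", -1.0)
    p[55] = frozen.heart_rate
    p[56] = frozen.lv_drive
    p[57] = frozen.rv_drive
    p[58] = frozen.venous_unstressed_delta
    p[59] = lv.activation_skew if lv.activation_shape == "skewed_half_sine" else 1.0
    p[60] = rv.activation_skew if rv.activation_shape == "skewed_half_sine" else 1.0
    p[61] = control.venous_max_delta
    return p


@dataclass
class SimulationResult:
    """Uniformly sampled traces plus the pacing log of one run."""

    frame: pd.DataFrame  # columns COLUMNS, one row per grid point
    beat_onsets: np.ndarray  # s, one entry per beat
    dt: float
    events_applied: list[tuple[float, str]] = field(default_factory=list)
    final_volumes: dict[str, float] = field(default_factory=dict)  # mL at t_end

    @property
    def duration(self) -> float:
        return float(self.frame["t"].iloc[-1])

    def window(self, t0: float, t1: float) -> pd.DataFrame:
        """Rows with ``t0 <= t < t1``."""
        t = self.frame["t"].to_numpy()
        i0 = int(np.searchsorted(t, t0 - 1e-12))
        i1 = int(np.searchsorted(t, t1 - 1e-12))
        return self.frame.iloc[i0:i1]


def integrate(network: NetworkSpec, controls: ctl.ControlSpec,
              t_span: tuple[float, float] = (0.0, 70.5), dt: float = 0.001,
              events: Sequence[tuple[float, Callable]] = (),
              engine: str = "numba",
              log: Optional[Callable[[str], None]] = None) -> SimulationResult:
    """Integrate the closed-loop model over ``t_span``.

    ``events`` is a time-sorted sequence of ``(time, apply)`` pairs; each
    ``apply(network, controls)`` mutates the specs and integration is
    restarted at that instant, so parameter changes are step-like and land
    exactly on the grid.  ``engine`` selects the numba-compiled kernel
    (default) or the pure-Python reference path (identical source).
    """
    if dt <= 0:
        raise ConfigurationError("integrate: dt must be > 0")
    t0, t1 = t_span
    if t1 <= t0:
        raise ConfigurationError("integrate: t_span must be increasing")
    network.validate(canonical=True)
    controls.validate()
    run = {"numba": _run_nb, "python": _run_py}.get(engine)
    if run is None:
        raise ConfigurationError(f"unknown engine {engine!r}")
    deriv = _deriv_nb if engine == "numba" else _deriv_py

    n_total = int(round((t1 - t0) / dt))
    out = np.empty((n_total + 1, len(COLUMNS)))
    beat_cap = int((t1 - t0) * 4.0) + 16
    beat_times = np.empty(beat_cap)
    n_beats = 0

    # initial state
    x = np.empty(10)
    comp = {c.name: c for c in network.compartments}
    x[0] = network.ventricles["lv"].initial_volume
    x[1] = comp["systemic_arteries"].initial_volume
    x[2] = comp["systemic_veins"].initial_volume
    x[3] = comp["right_atrium"].initial_volume
    x[4] = network.ventricles["rv"].initial_volume
    x[5] = comp["pulmonary_arteries"].initial_volume
    x[6] = comp["left_atrium"].initial_volume
    sa = comp["systemic_arteries"]
    x[7] = (x[1] - sa.unstressed_volume) / sa.compliance  # MAoP filter seed
    x[8] = controls.clamps.get("sy", controls.sy_baseline)
    x[9] = 0.0  # CO monitor spins up during settle-in

    frozen = ctl.apply_effectors(x[8], controls)
    prev_switches = dict(controls.switches)
    p = _pack(network, controls, frozen)

    # event step indices (each restart lands exactly on the grid)
    ev = []
    for te, apply_fn in events:
        step = int(round((te - t0) / dt))
        if not (0 <= step <= n_total):
            raise ConfigurationError(
                f"event at t={te} s is outside the integration span"
            )
        ev.append((step, te, apply_fn))
    ev.sort(key=lambda e: e[0])

    steps_into_beat, period_steps, hr_current = 0, 0, controls.hr_base
    applied: list[tuple[float, str, object]] = []
    seg_start = 0
    boundaries = [s for s, _, _ in ev] + [n_total]
    ei = 0
    for boundary in sorted(set(boundaries)):
        n_steps = boundary - seg_start
        if n_steps > 0:
            steps_into_beat, period_steps, hr_current, n_beats = run(
                x, p, out, seg_start, seg_start, n_steps, dt,
                steps_into_beat, period_steps, hr_current,
                beat_times, n_beats)
            seg = out[seg_start:boundary]
            bad = ~np.isfinite(seg) | (np.abs(seg[:, [1, 3]]) > PRESSURE_LIMIT).any(
                axis=1, keepdims=True)
            if bad.any():
                i_bad = int(np.argmax(bad.any(axis=1)))
                raise IntegrationError(
                    f"instability at t={seg[i_bad, 0]:.3f} s: pressure beyond "
                    f"{PRESSURE_LIMIT} mmHg or non-finite state"
                )
            seg_start = boundary
        # apply all events scheduled at this boundary
        while ei < len(ev) and ev[ei][0] == boundary:
            _, te, apply_fn = ev[ei]
            current = ctl.apply_effectors(x[8], controls)
            desc = apply_fn(network, controls)
            applied.append((te, desc if isinstance(desc, str) else "event"))
            if log is not None:
                log(f"t={te:.3f} s: {desc}")
            # freeze limbs that were just switched off at their last-on value
            for limb, attr in (("hr", "heart_rate"), ("lv_inotropy", "lv_drive"),
                               ("rv_inotropy", "rv_drive"),
                               ("venous_tone", "venous_unstressed_delta")):
                if prev_switches.get(limb, True) and not controls.switches.get(limb, True):
                    value = hr_current if limb == "hr" else getattr(current, attr)
                    setattr(frozen, attr, value)
            prev_switches = dict(controls.switches)
            if "sy" in controls.clamps:
                x[8] = controls.clamps["sy"]
            network.validate(canonical=True)
            controls.validate()
            p = _pack(network, controls, frozen)
            ei += 1

    # final sample at t1
    aux = np.empty(6)
    dxs = np.empty(10)
    deriv(x, p, steps_into_beat * dt, n_total * dt + t0, dxs, aux)
    out[n_total] = (t0 + n_total * dt, aux[0], x[7], aux[1], aux[2], x[9],
                    aux[4], aux[5], hr_current, x[0], aux[3])

    frame = pd.DataFrame(out, columns=list(COLUMNS))
    final_volumes = {
        "lv": x[0], "systemic_arteries": x[1], "systemic_veins": x[2],
        "right_atrium": x[3], "rv": x[4], "pulmonary_arteries": x[5],
        "left_atrium": x[6],
    }
    return SimulationResult(frame=frame,
                            beat_onsets=beat_times[:n_beats].copy(),
                            dt=dt, events_applied=applied,
                            final_volumes=final_volumes)
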