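"""Homeostatic (autonomic) negative-feedback controller.

A single sympathetic drive signal ``Sy`` (in FGU) is produced by
proportional feedback on low-pass-filtered mean aortic pressure (MAoP)
with a first-order actuator lag.  Sy drives three effector limbs, each
with its own on/off switch:

* heart rate — affine map, bounded;
* biventricular inotropic drive — identity (Sy in FGU feeds the
  ventricular gain element, which saturates at its limiter);
* venous tone — venoconstriction, a saturating reduction of the systemic
  venous unstressed volume (the "contractible volume of veins", CVV).

Reflex-syncope experiments disable the feedback and hold the controller
outputs at fixed values instead (``clamps``): clamped Sy still drives the
enabled effector maps; a clamped heart rate overrides the HR limb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .units import FGU_LIMIT

__all__ = [
    "ControlSpec",
    "EffectorOutputs",
    "filtered_maop",
    "update_sy",
    "apply_effectors",
    "syncope_mode",
    "SYNCOPE_CLAMPS",
]

#: (heart rate 1/min, Sy FGU) held in each reflex-syncope variant:
#: a — tachycardic, preserved drive; b — tachycardic, reduced drive;
#: c — bradycardic, reduced drive (cardioinhibitory); d — bradycardic,
#: raised drive.
SYNCOPE_CLAMPS: dict[str, tuple[float, float]] = {
    "a": (120.0, 1.0),
    "b": (120.0, 0.5),
    "c": (45.0, 0.5),
    "d": (45.0, 1.5),
}


@dataclass
class ControlSpec:
    """Setpoint, gains, effector maps, switches and clamp overrides."""

    maop_setpoint: float = 95.0  # mmHg
    maop_filter_tau: float = 2.0  # s
    feedback_gain: float = 0.15  # FGU per mmHg of pressure error
    sy_baseline: float = 1.0  # FGU
    sy_range: tuple[float, float] = (0.0, FGU_LIMIT)
    sy_tau: float = 2.0  # s, actuator lag
    hr_base: float = 70.0  # 1/min at Sy = sy_baseline
    hr_per_fgu: float = 25.0  # 1/min per FGU above baseline
    hr_bounds: tuple[float, float] = (30.0, 180.0)
    venous_ml_per_fgu: float = 150.0  # mL of CVV reduction per FGU
    venous_max_delta: float = 450.0  # mL, saturation of the venous-tone limb
    co_filter_tau: float = 3.0  # s, for the recorded CO trace
    switches: dict[str, bool] = field(
        default_factory=lambda: {
            "hr": True,
            "lv_inotropy": True,
            "rv_inotropy": True,
            "venous_tone": True,
        }
    )
    clamps: dict[str, float] = field(default_factory=dict)
    # "heart_rate" and/or "sy"

    def validate(self) -> None:
        lo, hi = self.sy_range
        if not (0.0 <= lo < hi <= FGU_LIMIT):
            raise ConfigurationError(
                f"sy_range must be within [0, {FGU_LIMIT}] FGU (got {self.sy_range})"
            )
        if not (lo <= self.sy_baseline <= hi):
            raise ConfigurationError("sy_baseline outside sy_range")
        if self.venous_max_delta <= 0:
            raise ConfigurationError("venous_max_delta must be > 0")
        for fname in ("maop_filter_tau", "sy_tau", "co_filter_tau"):
            if getattr(self, fname) <= 0:
                raise ConfigurationError(f"{fname} must be > 0")
        unknown = set(self.switches) - {"hr", "lv_inotropy", "rv_inotropy", "venous_tone"}
        if unknown:
            raise ConfigurationError(f"unknown switches: {sorted(unknown)}")
        unknown = set(self.clamps) - {"heart_rate", "sy"}
        if unknown:
            raise ConfigurationError(f"unknown clamps: {sorted(unknown)}")


@dataclass
class EffectorOutputs:
    """Controller outputs delivered to the hydraulic model."""

    heart_rate: float  # 1/min
    lv_drive: float  # FGU
    rv_drive: float  # FGU
    venous_unstressed_delta: float  # mL subtracted from venous V0


def filtered_maop(aop: "np.ndarray | list[float]", tau: float, dt: float,
                  initial: float | None = None) -> np.ndarray:
    """First-order low-pass of an aortic pressure trace.

    Uses the exact discrete step of the continuous filter, so a constant
    input is reproduced exactly and ``tau -> 0`` tracks the input.
    Returns the filtered trace (same length); the last element is the
    current MAoP.
    """
    u = np.asarray(aop, dtype=float)
    if u.size == 0:
        raise ConfigurationError("filtered_maop: empty pressure trace")
    alpha = 1.0 if tau <= 0 else -math.expm1(-dt / tau)
    y = np.empty_like(u)
    y[0] = u[0] if initial is None else initial + alpha * (u[0] - initial)
    for i in range(1, u.size):
        y[i] = y[i - 1] + alpha * (u[i] - y[i - 1])
    return y


def sy_target(maop: float, spec: ControlSpec) -> float:
    """Equilibrium Sy demanded by the proportional feedback law."""
    lo, hi = spec.sy_range
    raw = spec.sy_baseline + spec.feedback_gain * (spec.maop_setpoint - maop)
    return min(max(raw, lo), hi)


def update_sy(maop: float, spec: ControlSpec, sy_prev: float, dt: float) -> float:
    """Advance Sy one step of its first-order actuator dynamics.

    Sy relaxes toward ``sy_baseline + gain * (setpoint - MAoP)`` with time
    constant ``sy_tau`` and is clipped to ``sy_range``.  At ``maop ==
    setpoint`` the equilibrium is ``sy_baseline``; a clamped Sy is held
    fixed.
    """
    if dt <= 0:
        raise ConfigurationError("update_sy: dt must be > 0")
    if "sy" in spec.clamps:
        return spec.clamps["sy"]
    target = sy_target(maop, spec)
    sy = sy_prev + -math.expm1(-dt / spec.sy_tau) * (target - sy_prev)
    lo, hi = spec.sy_range
    return min(max(sy, lo), hi)


def apply_effectors(
    sy: float,
    spec: ControlSpec,
    frozen: EffectorOutputs | None = None,
) -> EffectorOutputs:
    """Map the drive signal Sy onto the three effector limbs.

    Limbs whose switch is off return their ``frozen`` last-on value
    (baseline values if no freeze state is supplied); a clamped heart rate
    or Sy overrides the corresponding input.
    """
    if "sy" in spec.clamps:
        sy = spec.clamps["sy"]
    if frozen is None:
        frozen = EffectorOutputs(spec.hr_base, spec.sy_baseline, spec.sy_baseline, 0.0)

    if "heart_rate" in spec.clamps:
        hr = spec.clamps["heart_rate"]
    elif spec.switches.get("hr", True):
        lo, hi = spec.hr_bounds
        hr = spec.hr_base + spec.hr_per_fgu * (sy - spec.sy_baseline)
        hr = min(max(hr, lo), hi)
    else:
        hr = frozen.heart_rate

    lv = sy if spec.switches.get("lv_inotropy", True) else frozen.lv_drive
    rv = sy if spec.switches.get("rv_inotropy", True) else frozen.rv_drive
    if spec.switches.get("venous_tone", True):
        ven = spec.venous_ml_per_fgu * (sy - spec.sy_baseline)
        m = spec.venous_max_delta
        ven = min(max(ven, -m), m)
    else:
        ven = frozen.venous_unstressed_delta
    return EffectorOutputs(hr, lv, rv, ven)


def syncope_mode(spec: ControlSpec, variant: str) -> ControlSpec:
    """Return a copy of ``spec`` configured for a reflex-syncope variant.

    Feedback is disabled by clamping both controller outputs: heart rate
    and Sy are held at the variant's fixed values (see
    :data:`SYNCOPE_CLAMPS`); the clamped Sy still drives every enabled
    effector map.
    """
    if variant not in SYNCOPE_CLAMPS:
        raise ConfigurationError(
            f"unknown syncope variant {variant!r}; expected one of "
            f"{sorted(SYNCOPE_CLAMPS)}"
        )
    hr, sy = SYNCOPE_CLAMPS[variant]
    clamps = dict(spec.clamps)
    clamps.update({"heart_rate": hr, "sy": sy})
    return replace(spec, clamps=clamps, switches=dict(spec.switches))
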