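"""Dotted parameter paths into (NetworkSpec, ControlSpec) pairs.

Scenario events address model parameters by strings such as
``lv.nominal_gain``, ``resistors.systemic_peripheral.resistance``,
``control.maop_setpoint``, ``control.clamps.heart_rate`` or
``control.switches.venous_tone``.  Resolution fails loudly, naming the
path, so malformed scenarios are rejected before a run starts.
"""

from __future__ import annotations

from typing import Any

from .control import ControlSpec
from .errors import ConfigurationError
from .network import NetworkSpec

__all__ = ["resolve", "get_value", "set_value"]

_CONTROL_DICTS = ("clamps", "switches")


def resolve(network: NetworkSpec, control: ControlSpec, path: str):
    """Return ``(container, key, is_attr)`` for a dotted parameter path."""
    parts = path.split(".")

    def fail(reason: str):
        raise ConfigurationError(f"cannot resolve target {path!r}: {reason}")

    if not parts or not all(parts):
        fail("empty path component")
    head = parts[0]
    if head in ("lv", "rv"):
        if network.ventricles is None or head not in network.ventricles:
            fail(f"network has no ventricle {head!r}")
        obj = network.ventricles[head]
        if len(parts) != 2 or not hasattr(obj, parts[1]):
            fail(f"no such ventricle field {'.'.join(parts[1:])!r}")
        return obj, parts[1], True
    if head == "control":
        if len(parts) == 2:
            if parts[1] in _CONTROL_DICTS:
                fail("clamps/switches need a key, e.g. control.clamps.sy")
            if not hasattr(control, parts[1]):
                fail(f"no such control field {parts[1]!r}")
            return control, parts[1], True
        if len(parts) == 3 and parts[1] in _CONTROL_DICTS:
            d = getattr(control, parts[1])
            valid = {"clamps": ("heart_rate", "sy"),
                     "switches": ("hr", "lv_inotropy", "rv_inotropy",
                                  "venous_tone")}[parts[1]]
            if parts[2] not in valid:
                fail(f"{parts[1]} key must be one of {valid}")
            return d, parts[2], False
        fail("malformed control path")
    if head == "resistors":
        if len(parts) != 3:
            fail("expected resistors.<name>.<field>")
        obj = network.resistor(parts[1])
        if parts[2] not in ("resistance", "one_way"):
            fail(f"no such resistor field {parts[2]!r}")
        return obj, parts[2], True
    if head == "compartments":
        if len(parts) != 3:
            fail("expected compartments.<name>.<field>")
        obj = network.compartment(parts[1])
        if not hasattr(obj, parts[2]):
            fail(f"no such compartment field {parts[2]!r}")
        return obj, parts[2], True
    if head == "respiration":
        if len(parts) != 2 or not hasattr(network.respiration, parts[1]):
            fail("no such respiration field")
        return network.respiration, parts[1], True
    fail("unknown root (expected lv, rv, control, resistors, compartments "
         "or respiration)")


def get_value(network: NetworkSpec, control: ControlSpec, path: str) -> Any:
    container, key, is_attr = resolve(network, control, path)
    if is_attr:
        return getattr(container, key)
    return container.get(key)


def set_value(network: NetworkSpec, control: ControlSpec, path: str,
              value: Any) -> None:
    container, key, is_attr = resolve(network, control, path)
    if is_attr:
        setattr(container, key, value)
    elif value is None:
        container.pop(key, None)
    else:
        container[key] = value
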