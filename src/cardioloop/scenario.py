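"""Timed experimental protocols (scenarios) and their execution.

A scenario is an ordered list of instantaneous parameter changes applied
to a network/controller pair during one continuous run.  The builtin
``paper_full_*`` scenarios encode the five-phase exertional-syncope
protocol for a heart developing severe aortic valve stenosis:

======  =================================================================
time    change
======  =================================================================
 50 s   (display convention: everything before ~50 s is settle-in)
 70.5   LV contractility failure: nominal gain 100 -> 20
110.5   severe aortic stenosis: LV output series resistance added
150.5   exercise: peripheral resistance halved, MAoP setpoint raised
240.5   reflex syncope: feedback replaced by fixed HR / Sy clamps
======  =================================================================

Variants a-d differ only in the clamps applied at 240.5 s (see
:data:`cardioloop.control.SYNCOPE_CLAMPS`).  Events are steps, not ramps,
and the integrator restarts at each event time, so a parameter sampled
just before an event still has its old value and just after has the new
one.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import io as _io
from . import model, paths
from .control import SYNCOPE_CLAMPS, ControlSpec
from .errors import ConfigurationError
from .network import NetworkSpec

__all__ = [
    "ScenarioEvent",
    "Scenario",
    "AVS_RESISTANCE",
    "PHASE_WINDOWS",
    "BUILTIN_NAMES",
    "builtin_scenario",
    "parse_scenario",
    "serialize_scenario",
    "run",
]

#: Output series resistance (U) of the severely stenotic aortic valve,
#: calibrated to give a ~50 mmHg sedentary transvalvular gradient at
#: preserved stroke volume (rising to ~70 mmHg in exercise).
AVS_RESISTANCE = 0.039

#: Exercise raises the regulated MAoP setpoint by this much (mmHg); the
#: magnitude is a calibration constant of the default parameter set.
EXERCISE_SETPOINT_RESET = 44.0

#: One-cycle analysis windows (s) printed for each protocol phase.
PHASE_WINDOWS = {
    "baseline": (68.7, 69.3),
    "low_contractility": (103.7, 104.3),
    "avs": (148.7, 149.3),
    "exercise": (233.7, 234.3),
    "syncope": (543.7, 544.3),
}

BUILTIN_NAMES = ("baseline", "paper_full_a", "paper_full_b", "paper_full_c",
                 "paper_full_d")


@dataclass
class ScenarioEvent:
    """One instantaneous parameter change."""

    time: float  # s
    target: str  # dotted path, e.g. "lv.nominal_gain"
    value: object

    def validate(self, network: NetworkSpec, control: ControlSpec) -> None:
        if self.time < 0:
            raise ConfigurationError(f"event time must be >= 0 (got {self.time})")
        paths.resolve(network, control, self.target)


@dataclass
class Scenario:
    """A named protocol: duration, step size and time-ordered events."""

    name: str
    duration: float  # s
    dt: float = 0.001  # s
    events: list[ScenarioEvent] = field(default_factory=list)
    record: list[str] = field(default_factory=lambda: list(model.COLUMNS))

    def validate(self, network: NetworkSpec, control: ControlSpec) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ConfigurationError("scenario duration and dt must be > 0")
        times = [e.time for e in self.events]
        if times and max(times) > self.duration:
            raise ConfigurationError(
                f"scenario {self.name!r}: duration ({self.duration} s) must "
                f"cover the last event ({max(times)} s)"
            )
        if times != sorted(times):
            warnings.warn(
                f"scenario {self.name!r}: events were not time-ordered; "
                "sorting", stacklevel=2)
            self.events.sort(key=lambda e: e.time)
        for e in self.events:
            e.validate(network, control)
        unknown = set(self.record) - set(model.COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown record variables: {sorted(unknown)}"
            )


def builtin_scenario(name: str,
                     params: Optional[tuple[NetworkSpec, ControlSpec]] = None
                     ) -> Scenario:
    """Return a builtin protocol.

    ``baseline`` is the sedentary normal heart (no events, 70.5 s);
    ``paper_full_a`` … ``paper_full_d`` are the full 550 s five-phase
    protocols differing only in the syncope variant.  Relative changes
    (halved peripheral resistance, +25 mmHg setpoint reset) are computed
    against the supplied parameter set (the frozen defaults if omitted).
    """
    if name == "baseline":
        return Scenario(name="baseline", duration=70.5)
    if name not in BUILTIN_NAMES:
        raise ConfigurationError(
            f"unknown builtin scenario {name!r}; expected one of {BUILTIN_NAMES}"
        )
    variant = name[-1]
    network, control = params if params is not None else _io.load_params()
    r_sys = network.resistor("systemic_peripheral").resistance
    hr_clamp, sy_clamp = SYNCOPE_CLAMPS[variant]
    events = [
        ScenarioEvent(70.5, "lv.nominal_gain", 20.0),
        ScenarioEvent(110.5, "lv.output_series_resistance", AVS_RESISTANCE),
        ScenarioEvent(150.5, "resistors.systemic_peripheral.resistance",
                      r_sys / 2.0),
        ScenarioEvent(150.5, "control.maop_setpoint",
                      control.maop_setpoint + EXERCISE_SETPOINT_RESET),
        ScenarioEvent(240.5, "control.clamps.heart_rate", hr_clamp),
        ScenarioEvent(240.5, "control.clamps.sy", sy_clamp),
    ]
    return Scenario(name=name, duration=550.0, events=events)


def parse_scenario(document, network: Optional[NetworkSpec] = None,
                   control: Optional[ControlSpec] = None) -> Scenario:
    """Parse a scenario from YAML/JSON text or an already-loaded mapping.

    Unknown target paths are rejected (validated against the supplied
    specs, or the frozen defaults); unsorted events are sorted with a
    warning.
    """
    if isinstance(document, str):
        doc = yaml.safe_load(document)
    else:
        doc = document
    if not isinstance(doc, dict):
        raise ConfigurationError("scenario document must be a mapping")
    unknown = set(doc) - {"name", "duration", "dt", "events", "record"}
    if unknown:
        raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
    try:
        events = [
            ScenarioEvent(float(e["time"]), str(e["target"]), e["value"])
            for e in doc.get("events", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(
            f"each event needs time/target/value fields ({exc})"
        ) from None
    sc = Scenario(
        name=str(doc.get("name", "unnamed")),
        duration=float(doc["duration"]),
        dt=float(doc.get("dt", 0.001)),
        events=events,
        record=list(doc.get("record", model.COLUMNS)),
    )
    if network is None or control is None:
        network, control = _io.load_params()
    sc.validate(network, control)
    return sc


def serialize_scenario(scenario: Scenario) -> dict:
    """Normalized mapping form of a scenario (round-trips with parse)."""
    return {
        "name": scenario.name,
        "duration": scenario.duration,
        "dt": scenario.dt,
        "events": [
            {"time": e.time, "target": e.target, "value": e.value}
            for e in sorted(scenario.events, key=lambda e: e.time)
        ],
        "record": list(scenario.record),
    }


def run(scenario: Scenario, network: Optional[NetworkSpec] = None,
        control: Optional[ControlSpec] = None, engine: str = "numba",
        log=None) -> model.SimulationResult:
    """Execute a scenario and return one contiguous result over [0, duration].

    The supplied specs are deep-copied first, so a scenario never mutates
    its inputs; identical inputs give identical outputs.
    """
    if network is None or control is None:
        network, control = _io.load_params()
    network = copy.deepcopy(network)
    control = copy.deepcopy(control)
    scenario.validate(network, control)

    def make_apply(event: ScenarioEvent):
        def apply(net, con):
            paths.set_value(net, con, event.target, event.value)
            return f"{event.target} <- {event.value!r}"
        return apply

    events = [(e.time, make_apply(e)) for e in scenario.events]
    return model.integrate(network, control, (0.0, scenario.duration),
                           dt=scenario.dt, events=events, engine=engine,
                           log=log)
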