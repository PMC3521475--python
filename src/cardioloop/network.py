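"""Domain types describing the closed-loop hydraulic network.

The circulation is modelled as an eight-element closed loop: two actively
contracting ventricles plus six passive compliance compartments connected
by resistors, four of which are one-way valves (ideal diodes: zero reverse
flow).  Canonical loop order::

    LV -> aortic valve -> systemic arteries -> peripheral resistance
       -> systemic veins -> venous return -> right atrium -> tricuspid
       -> RV -> pulmonary valve -> pulmonary arteries -> pulmonary
       resistance -> pulmonary veins / left atrium -> mitral -> LV

Compartments flagged ``intrathoracic`` are referenced to the respiration
waveform (sub-atmospheric, fluctuating intrathoracic pressure); the rest
are referenced to ambient pressure.  Atria are passive reservoirs and do
not contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigurationError

__all__ = [
    "CompartmentSpec",
    "ResistorSpec",
    "VentricleSpec",
    "RespirationSpec",
    "NetworkSpec",
    "HemoState",
    "CANONICAL_COMPARTMENTS",
    "CANONICAL_RESISTORS",
]

#: Names of the passive compartments, in canonical loop order.
CANONICAL_COMPARTMENTS = (
    "systemic_arteries",
    "systemic_veins",
    "right_atrium",
    "pulmonary_arteries",
    "left_atrium",
)

#: Canonical resistor list as (name, upstream, downstream, one_way).
CANONICAL_RESISTORS = (
    ("aortic_valve", "lv", "systemic_arteries", True),
    ("systemic_peripheral", "systemic_arteries", "systemic_veins", False),
    ("venous_return", "systemic_veins", "right_atrium", False),
    ("tricuspid_valve", "right_atrium", "rv", True),
    ("pulmonary_valve", "rv", "pulmonary_arteries", True),
    ("pulmonary_peripheral", "pulmonary_arteries", "left_atrium", False),
    ("mitral_valve", "left_atrium", "lv", True),
)


@dataclass
class CompartmentSpec:
    """A passive vascular compartment (a compliance element).

    Transmural pressure is ``(volume - unstressed_volume) / compliance``;
    the absolute pressure adds the intrathoracic pressure when the
    compartment lies inside the thorax.
    """

    name: str
    compliance: float  # mL/mmHg
    unstressed_volume: float  # mL
    initial_volume: float  # mL
    external_pressure_source: str = "ambient"  # "ambient" | "intrathoracic"

    def validate(self) -> None:
        if self.compliance <= 0:
            raise ConfigurationError(
                f"compartment {self.name!r}: compliance must be > 0 "
                f"(got {self.compliance})"
            )
        if self.unstressed_volume < 0 or self.initial_volume < 0:
            raise ConfigurationError(
                f"compartment {self.name!r}: volumes must be >= 0"
            )
        if self.external_pressure_source not in ("ambient", "intrathoracic"):
            raise ConfigurationError(
                f"compartment {self.name!r}: external_pressure_source must be "
                f"'ambient' or 'intrathoracic'"
            )


@dataclass
class ResistorSpec:
    """A flow resistance between two compartments; optionally a valve."""

    name: str
    upstream: str
    downstream: str
    resistance: float  # U = mmHg*s/mL
    one_way: bool = False

    def validate(self) -> None:
        if self.resistance <= 0:
            raise ConfigurationError(
                f"resistor {self.name!r}: resistance must be > 0 "
                f"(got {self.resistance})"
            )


@dataclass
class VentricleSpec:
    """An actively contracting chamber (time-varying elastance).

    Chamber pressure is::

        P = a(t) * E_max_eff * (V - V0) + (V - V0) / C_passive + ITP

    where ``a(t)`` is the activation waveform (support exactly
    ``systole_duration`` seconds, independent of heart rate) and
    ``E_max_eff`` scales with the nominal gain and the inotropic drive
    (saturating at ``limiter_max`` FGU).  ``nominal_gain`` is the
    contractility dial: 100 is a normal left ventricle, about 20 a failing
    one.  ``output_series_resistance`` is an extra resistance added in
    series with the outflow valve; a severe aortic stenosis is modelled by
    raising it from 0.
    """

    name: str  # "lv" | "rv"
    nominal_gain: float = 100.0  # dimensionless
    e_max_ref: float = 2.0  # mmHg/mL at nominal_gain 100, zero drive
    systole_duration: float = 0.2  # s, heart-rate independent
    activation_shape: str = "skewed_half_sine"
    activation_skew: float = 1.45  # >1 moves the activation peak past mid-systole
    passive_compliance: float = 10.0  # mL/mmHg
    diastolic_relaxation_tau: float = 0.05  # s
    limiter_max: float = 8.0  # FGU
    inotropic_slope: float = 0.5  # gain multiplier per FGU of drive
    unstressed_volume: float = 10.0  # mL
    initial_volume: float = 130.0  # mL
    output_series_resistance: float = 0.0  # U
    external_pressure_source: str = "intrathoracic"

    def validate(self) -> None:
        if self.name not in ("lv", "rv"):
            raise ConfigurationError(
                f"ventricle name must be 'lv' or 'rv' (got {self.name!r})"
            )
        if self.systole_duration <= 0:
            raise ConfigurationError(
                f"ventricle {self.name!r}: systole_duration must be > 0"
            )
        if self.activation_shape not in ("half_sine", "skewed_half_sine"):
            raise ConfigurationError(
                f"ventricle {self.name!r}: unknown activation_shape "
                f"{self.activation_shape!r}"
            )
        if self.activation_skew <= 0:
            raise ConfigurationError(
                f"ventricle {self.name!r}: activation_skew must be > 0"
            )
        for fname in ("e_max_ref", "passive_compliance", "nominal_gain"):
            if getattr(self, fname) <= 0:
                raise ConfigurationError(
                    f"ventricle {self.name!r}: {fname} must be > 0"
                )
        if self.output_series_resistance < 0:
            raise ConfigurationError(
                f"ventricle {self.name!r}: output_series_resistance must be >= 0"
            )
        if self.limiter_max <= 0:
            raise ConfigurationError(
                f"ventricle {self.name!r}: limiter_max must be > 0"
            )


@dataclass
class RespirationSpec:
    """Sinusoidal intrathoracic pressure source.

    ``mean_itp`` must be negative: the thoracic cavity is sub-atmospheric,
    which is what allows early-diastolic ventricular pressure to dip
    slightly below zero.
    """

    mean_itp: float = -4.0  # mmHg
    amplitude: float = 2.0  # mmHg
    period: float = 4.0  # s
    waveform: str = "sinusoid"

    def validate(self) -> None:
        if self.mean_itp >= 0:
            raise ConfigurationError(
                f"respiration: mean_itp must be < 0 (got {self.mean_itp})"
            )
        if self.period <= 0:
            raise ConfigurationError("respiration: period must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("respiration: amplitude must be >= 0")
        if self.waveform != "sinusoid":
            raise ConfigurationError(
                f"respiration: unknown waveform {self.waveform!r}"
            )


@dataclass
class NetworkSpec:
    """The full circulatory topology.

    ``ventricles`` may be None for passive test networks (e.g. an RC
    discharge pair); the canonical closed-loop model requires both.
    """

    compartments: list[CompartmentSpec]
    resistors: list[ResistorSpec]
    ventricles: Optional[dict[str, VentricleSpec]] = None
    respiration: RespirationSpec = field(default_factory=RespirationSpec)
    total_blood_volume: Optional[float] = None  # mL; derived if omitted

    def __post_init__(self) -> None:
        if self.total_blood_volume is None:
            self.total_blood_volume = sum(
                c.initial_volume for c in self.compartments
            ) + sum(v.initial_volume for v in (self.ventricles or {}).values())

    # -- lookups ---------------------------------------------------------
    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown compartment {name!r}")

    def resistor(self, name: str) -> ResistorSpec:
        for r in self.resistors:
            if r.name == name:
                return r
        raise ConfigurationError(f"unknown resistor {name!r}")

    def node_names(self) -> list[str]:
        names = [c.name for c in self.compartments]
        if self.ventricles:
            names.extend(self.ventricles)
        return names

    # -- validation ------------------------------------------------------
    def validate(self, canonical: bool = False) -> None:
        """Check structural invariants; ``canonical=True`` additionally
        requires the full closed-loop topology of the default model."""
        names = self.node_names()
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate compartment names")
        for c in self.compartments:
            c.validate()
        for v in (self.ventricles or {}).values():
            v.validate()
        self.respiration.validate()
        for r in self.resistors:
            r.validate()
            for end in (r.upstream, r.downstream):
                if end not in names:
                    raise ConfigurationError(
                        f"resistor {r.name!r}: endpoint {end!r} is not a "
                        f"known compartment"
                    )
        init_total = sum(c.initial_volume for c in self.compartments) + sum(
            v.initial_volume for v in (self.ventricles or {}).values()
        )
        if self.total_blood_volume is not None and abs(
            init_total - self.total_blood_volume
        ) > 1e-6:
            raise ConfigurationError(
                f"total_blood_volume ({self.total_blood_volume}) does not "
                f"equal the sum of initial compartment volumes ({init_total})"
            )
        if canonical:
            self._validate_canonical()

    def _validate_canonical(self) -> None:
        if self.ventricles is None or set(self.ventricles) != {"lv", "rv"}:
            raise ConfigurationError(
                "canonical network requires ventricles 'lv' and 'rv'"
            )
        have = {c.name for c in self.compartments}
        want = set(CANONICAL_COMPARTMENTS)
        if have != want:
            raise ConfigurationError(
                f"canonical network requires compartments {sorted(want)}; "
                f"got {sorted(have)}"
            )
        by_name = {r.name: r for r in self.resistors}
        for name, up, down, one_way in CANONICAL_RESISTORS:
            r = by_name.get(name)
            if r is None:
                raise ConfigurationError(f"canonical resistor {name!r} missing")
            if (r.upstream, r.downstream, r.one_way) != (up, down, one_way):
                raise ConfigurationError(
                    f"resistor {name!r} must connect {up} -> {down} "
                    f"(one_way={one_way})"
                )
        if len(self.resistors) != len(CANONICAL_RESISTORS):
            raise ConfigurationError(
                "canonical network must contain exactly the seven loop "
                "resistors"
            )


@dataclass
class HemoState:
    """Instantaneous hemodynamic state of the closed-loop model."""

    t: float  # s
    volumes: dict[str, float]  # mL, keyed by compartment/ventricle name
    cardiac_phase: float  # s since last beat onset
    sy: float  # FGU
    heart_rate: float  # 1/min

    def validate(self) -> None:
        for name, v in self.volumes.items():
            if v < 0:
                raise ConfigurationError(
                    f"volume of {name!r} is negative ({v} mL)"
                )
        period = 60.0 / self.heart_rate
        if not (0 <= self.cardiac_phase < period + 1e-12):
            raise ConfigurationError(
                f"cardiac_phase {self.cardiac_phase} outside [0, {period})"
            )


def clone(spec):
    """Shallow-copy helper for dataclass specs (used by the scenario engine)."""
    return replace(spec)
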