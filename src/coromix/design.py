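"""Experimental design: flow/infusion protocols, geometry, and mixing arithmetic.

Continuous-infusion thermodilution estimates absolute coronary blood flow from
the steady temperature of room-temperature saline continuously infused into
blood through a microcatheter.  The assessment compares two catheter
topologies in a 4 mm coronary-artery model:

* ``SIDE_HOLE`` — monorail infusion catheter with four 100 um side holes and
  the 0.36 mm pressure/temperature wire running *inside* its lumen;
* ``END_HOLE`` — conventional microcatheter with a single end hole and the
  wire running *alongside*.

Every other module draws its parameters (flow grid, temperatures, geometry)
from this one, so the study design is defined in a single validated place.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .errors import GeometryError, InvalidProtocolError

__all__ = [
    "FlowCategory",
    "CatheterType",
    "WirePlacement",
    "FlowProtocol",
    "VesselCatheterGeometry",
    "BLOOD_TEMPERATURE_C",
    "INFUSATE_EXIT_TEMPERATURE_C",
    "BENCH_INFUSATE_TEMPERATURE_C",
    "clinically_relevant_combinations",
    "cfd_combinations",
    "perfect_mix_fraction",
    "perfect_mix_temperature",
]

#: Temperature of the blood(-mimicking) fluid, degC.
BLOOD_TEMPERATURE_C = 37.0
#: Infusate temperature as it exits the catheter in the simulated mode, degC
#: (room-temperature saline warms while travelling through the catheter in
#: the body, so the exit temperature is above room temperature).
INFUSATE_EXIT_TEMPERATURE_C = 29.0
#: Infusate temperature in the bench mode (room-temperature saline), degC.
BENCH_INFUSATE_TEMPERATURE_C = 23.0

#: Mean coronary flow per category, mL/min.
CATEGORY_FLOW_ML_MIN = {"LOW": 50.0, "MED": 150.0, "HIGH": 250.0}

#: The nine clinically used (category, infusion rate) cells: per flow
#: category only a narrow band of infusion rates keeps a usable
#: signal-to-noise ratio without perturbing the coronary physiology.
CLINICAL_GRID = {
    "LOW": (8.0, 10.0, 15.0),
    "MED": (15.0, 20.0, 25.0),
    "HIGH": (20.0, 25.0, 30.0),
}

#: The four cells per catheter that are run through the transport simulator.
SIMULATED_CELLS = (("LOW", 8.0), ("LOW", 15.0), ("MED", 15.0), ("HIGH", 25.0))

_ALLOWED_RATES = frozenset({8.0, 10.0, 15.0, 20.0, 25.0, 30.0})


class FlowCategory(str, enum.Enum):
    """Coronary-flow regime from resting to maximal hyperaemic flow."""

    LOW = "LOW"
    MED = "MED"
    HIGH = "HIGH"

    @property
    def mean_flow_ml_min(self) -> float:
        return CATEGORY_FLOW_ML_MIN[self.value]


class CatheterType(str, enum.Enum):
    SIDE_HOLE = "SIDE_HOLE"
    END_HOLE = "END_HOLE"


class WirePlacement(str, enum.Enum):
    INSIDE = "INSIDE"
    ALONGSIDE = "ALONGSIDE"


@dataclass(frozen=True)
class FlowProtocol:
    """One coronary-flow / infusion-rate combination.

    Parameters
    ----------
    coronary_category
        LOW / MED / HIGH regime; must match ``coronary_flow_mean``.
    coronary_flow_mean
        Mean coronary flow, mL/min (50, 150 or 250).
    infusion_rate
        Continuous saline infusion rate, mL/min.
    blood_temperature
        Temperature of the blood-side fluid, degC.
    infusate_exit_temperature
        Infusate temperature where it leaves the catheter, degC.  29 degC in
        the simulated mode, 23 degC (room temperature) in the bench mode.
    catheter
        Injection topology, side-hole or end-hole.
    cardiac_period
        Cardiac cycle length, s.
    """

    coronary_category: FlowCategory
    coronary_flow_mean: float
    infusion_rate: float
    catheter: CatheterType
    blood_temperature: float = BLOOD_TEMPERATURE_C
    infusate_exit_temperature: float = INFUSATE_EXIT_TEMPERATURE_C
    cardiac_period: float = 1.0

    def __post_init__(self) -> None:
        cat = FlowCategory(self.coronary_category)
        object.__setattr__(self, "coronary_category", cat)
        object.__setattr__(self, "catheter", CatheterType(self.catheter))
        if self.coronary_flow_mean != cat.mean_flow_ml_min:
            raise InvalidProtocolError(
                f"coronary_flow_mean={self.coronary_flow_mean} does not match "
                f"category {cat.value} ({cat.mean_flow_ml_min} mL/min)"
            )
        if self.infusion_rate != 0.0:  # rate 0 = no-infusion control
            if self.infusion_rate not in _ALLOWED_RATES:
                raise InvalidProtocolError(
                    f"infusion_rate={self.infusion_rate} outside the studied "
                    f"set {sorted(_ALLOWED_RATES)}"
                )
            if self.infusion_rate not in CLINICAL_GRID[cat.value]:
                raise InvalidProtocolError(
                    f"({cat.value}, {self.infusion_rate}) is not one of the "
                    "nine clinically used combinations"
                )
        if not (0.0 < self.infusate_exit_temperature < self.blood_temperature):
            raise InvalidProtocolError(
                "infusate exit temperature must lie strictly between 0 degC "
                "and the blood temperature"
            )
        if self.cardiac_period <= 0:
            raise InvalidProtocolError("cardiac_period must be positive")

    @property
    def label(self) -> str:
        return (
            f"{self.catheter.value.lower()}_{self.coronary_category.value}"
            f"_{self.infusion_rate:g}"
        )


@dataclass(frozen=True)
class VesselCatheterGeometry:
    """Idealized straight-vessel geometry with a coaxial catheter.

    Lengths in mm except the side-hole diameter (um).  The catheter is a
    straight tube whose outlet(s) sit ``outlet_axial_position`` into the
    vessel; the pressure/temperature wire runs inside the catheter
    (side-hole) or alongside it (end-hole) and continues distally to carry
    the sensor.
    """

    vessel_diameter: float = 4.0
    vessel_length: float = 70.0
    catheter_outer_diameter: float = 0.84
    catheter_inner_diameter: float = 0.60
    wire_diameter: float = 0.36
    outlet_axial_position: float = 10.0
    side_hole_diameter_um: float = 100.0
    side_hole_count: int = 4
    wire_placement: WirePlacement = WirePlacement.INSIDE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wire_placement", WirePlacement(self.wire_placement)
        )
        if not (
            0.0
            < self.wire_diameter
            < self.catheter_outer_diameter
            < self.vessel_diameter
        ):
            raise GeometryError(
                "require 0 < wire diameter < catheter OD < vessel diameter"
            )
        if not (0.0 < self.catheter_inner_diameter < self.catheter_outer_diameter):
            raise GeometryError("catheter ID must lie in (0, catheter OD)")
        if not (0.0 < self.outlet_axial_position < self.vessel_length):
            raise GeometryError("outlet must lie strictly inside the vessel")
        if self.side_hole_count < 1 or self.side_hole_diameter_um <= 0:
            raise GeometryError("side holes must have positive count and size")

    @property
    def vessel_radius(self) -> float:
        return self.vessel_diameter / 2.0

    @property
    def catheter_radius(self) -> float:
        return self.catheter_outer_diameter / 2.0

    @property
    def wire_radius(self) -> float:
        return self.wire_diameter / 2.0

    @classmethod
    def for_catheter(cls, catheter: CatheterType, **overrides) -> "VesselCatheterGeometry":
        """Default geometry for a catheter type (wire inside vs alongside)."""
        placement = (
            WirePlacement.INSIDE
            if CatheterType(catheter) is CatheterType.SIDE_HOLE
            else WirePlacement.ALONGSIDE
        )
        return cls(wire_placement=placement, **overrides)


def _protocols_for(cells, catheters, infusate_temperature, cardiac_period):
    out = []
    for cath in catheters:
        for category, rate in cells:
            out.append(
                FlowProtocol(
                    coronary_category=FlowCategory(category),
                    coronary_flow_mean=CATEGORY_FLOW_ML_MIN[category],
                    infusion_rate=rate,
                    catheter=cath,
                    infusate_exit_temperature=infusate_temperature,
                    cardiac_period=cardiac_period,
                )
            )
    return out


def clinically_relevant_combinations(
    catheter: CatheterType | None = None,
    *,
    bench: bool = False,
    cardiac_period: float = 1.0,
) -> list[FlowProtocol]:
    """The nine clinically used flow/infusion combinations per catheter.

    Returns 18 protocols (9 per catheter type), or 9 when ``catheter`` is
    given.  ``bench=True`` selects the bench-mode infusate temperature
    (23 degC room-temperature saline) instead of the simulated-mode catheter
    exit temperature (29 degC).
    """
    cells = [(cat, r) for cat, rates in CLINICAL_GRID.items() for r in rates]
    catheters = [CatheterType(catheter)] if catheter is not None else list(CatheterType)
    ti = BENCH_INFUSATE_TEMPERATURE_C if bench else INFUSATE_EXIT_TEMPERATURE_C
    return _protocols_for(cells, catheters, ti, cardiac_period)


def cfd_combinations(
    catheter: CatheterType | None = None,
    *,
    bench: bool = False,
    cardiac_period: float = 1.0,
) -> list[FlowProtocol]:
    """The four flow/infusion cells simulated per catheter type.

    These are the subset of the clinical grid carried through the transport
    simulator: (LOW, 8), (LOW, 15), (MED, 15) and (HIGH, 25) mL/min.
    """
    catheters = [CatheterType(catheter)] if catheter is not None else list(CatheterType)
    ti = BENCH_INFUSATE_TEMPERATURE_C if bench else INFUSATE_EXIT_TEMPERATURE_C
    return _protocols_for(SIMULATED_CELLS, catheters, ti, cardiac_period)


def perfect_mix_fraction(coronary_flow: float, infusion_rate: float) -> float:
    """Well-mixed dilution fraction ``P* = Qi / (Qb + Qi)``.

    The volume fraction of infusate in the fully mixed downstream fluid;
    equivalently, the dilution probability that a perfectly mixed
    temperature reading maps back to.
    """
    if coronary_flow <= 0:
        raise InvalidProtocolError("coronary flow must be positive")
    if infusion_rate < 0:
        raise InvalidProtocolError("infusion rate must be non-negative")
    return infusion_rate / (coronary_flow + infusion_rate)


def mixed_cup_temperature(
    coronary_flow: float, infusion_rate: float, tb: float, ti: float
) -> float:
    """Flow-weighted mean of two streams, ``Tb - P* (Tb - Ti)``, degC."""
    pstar = perfect_mix_fraction(coronary_flow, infusion_rate)
    return tb - pstar * (tb - ti)


def perfect_mix_temperature(protocol: FlowProtocol) -> float:
    """Flow-weighted mean temperature ``Tmix = Tb - P* (Tb - Ti)``, degC.

    The mixed-cup temperature downstream of the infusion site once blood at
    ``Tb`` and infusate at ``Ti`` are fully mixed, by energy balance of the
    two streams.
    """
    return mixed_cup_temperature(
        protocol.coronary_flow_mean,
        protocol.infusion_rate,
        protocol.blood_temperature,
        protocol.infusate_exit_temperature,
    )


def with_infusate_temperature(protocol: FlowProtocol, ti: float) -> FlowProtocol:
    """Copy of ``protocol`` with a different infusate exit temperature."""
    return replace(protocol, infusate_exit_temperature=ti)
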