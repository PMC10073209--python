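"""Coil geometry/drive description and closed-form design estimates.

A flat spiral coil is described by its inner diameter, number of turns,
conductor cross-section and turn spacing.  Three closed-form quantities are
derived from it: a mean winding radius (the "area parameter"), the
flat-spiral (Wheeler) inductance, and a centre-field estimate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from typing import Any, Mapping

from .constants import MM_PER_INCH, MU_0

__all__ = [
    "CoilSpec",
    "DesignEstimates",
    "RadiusConvention",
    "SpecValidationError",
    "coil_area",
    "wheeler_inductance",
    "peak_field_estimate",
    "design_report",
    "spiral_area_param",
    "wheeler_inductance_uH",
    "spec_from_dict",
    "spec_to_dict",
    "default_mouse_coil",
    "generic_human_coil",
]


class SpecValidationError(ValueError):
    """A coil specification violates one of its invariants."""


class RadiusConvention(str, Enum):
    """Which radius plays the role of R in the centre-field estimate."""

    inner_radius = "inner_radius"
    outer_radius = "outer_radius"
    mean_radius = "mean_radius"


@dataclass(frozen=True)
class CoilSpec:
    """Geometric and drive parameters of a single coil.

    Lengths are millimetres, current amperes (peak), voltage volts and
    ``frequency_Hz`` the pulse repetition rate.  ``outer_diameter_mm`` may be
    omitted, in which case it is derived from the spiral growth law
    ``Di + 2 N (W + S)``.
    """

    topology: str = "circular"
    inner_diameter_mm: float = 20.0
    turns: int = 7
    wire_width_mm: float = 3.0
    wire_height_mm: float = 2.0
    turn_gap_mm: float = 0.2
    current_A: float = 1000.0
    voltage_V: float = 500.0
    frequency_Hz: float = 20.0
    outer_diameter_mm: float | None = None
    label: str = "coil"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "figure8"):
            raise SpecValidationError(
                f"topology must be 'circular' or 'figure8', got {self.topology!r}"
            )
        if self.inner_diameter_mm <= 0:
            raise SpecValidationError("invariant Di > 0 violated")
        if self.turns < 1:
            raise SpecValidationError("invariant N >= 1 violated")
        if self.wire_width_mm <= 0:
            raise SpecValidationError("invariant W > 0 violated")
        if self.wire_height_mm <= 0:
            raise SpecValidationError("invariant wire height > 0 violated")
        if self.turn_gap_mm < 0:
            raise SpecValidationError("invariant S >= 0 violated")
        if self.current_A < 0:
            raise SpecValidationError("invariant I >= 0 violated")
        pitch = self.wire_width_mm + self.turn_gap_mm
        if self.outer_diameter_mm is not None:
            grown = self.inner_diameter_mm + 2 * self.turns * pitch
            if abs(self.outer_diameter_mm - grown) > pitch:
                raise SpecValidationError(
                    "invariant |Do - (Di + 2 N (W+S))| <= (W+S) violated: "
                    f"Do={self.outer_diameter_mm} vs grown {grown}"
                )

    @property
    def effective_outer_diameter_mm(self) -> float:
        """Outer diameter implied by the spiral growth law (ignores any
        independently stated Do)."""
        return self.inner_diameter_mm + 2 * self.turns * (
            self.wire_width_mm + self.turn_gap_mm
        )


@dataclass(frozen=True)
class DesignEstimates:
    area_mm: float
    inductance_uH: float
    peak_field_T: float
    radius_convention: RadiusConvention

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["radius_convention"] = self.radius_convention.value
        return json.dumps(d, indent=2)


def spiral_area_param(Di: float, N: int, W: float, S: float) -> float:
    """Mean-radius parameter A = (Di + N (W + S)) / 2, same unit as Di.

    Defined for N >= 0; N = 0 collapses to the inner radius.
    """
    if Di <= 0:
        raise SpecValidationError("invariant Di > 0 violated")
    if N < 0:
        raise SpecValidationError("turn count must be non-negative")
    return (Di + N * (W + S)) / 2.0


def coil_area(spec: CoilSpec) -> float:
    """Area parameter of the spiral in millimetres."""
    return spiral_area_param(
        spec.inner_diameter_mm, spec.turns, spec.wire_width_mm, spec.turn_gap_mm
    )


def wheeler_inductance_uH(
    Di: float, N: int, W: float, S: float, unit: str = "mm"
) -> float:
    """Flat-spiral inductance L = N^2 A^2 / (30 A - 11 Di) in microhenry.

    The empirical formula yields microhenries when lengths are expressed in
    inches; ``unit`` declares the unit of the inputs ("mm" or "inch") and the
    conversion is applied internally.
    """
    if unit == "mm":
        scale = 1.0 / MM_PER_INCH
    elif unit == "inch":
        scale = 1.0
    else:
        raise ValueError(f"unit must be 'mm' or 'inch', got {unit!r}")
    if N == 0:
        return 0.0
    a_in = spiral_area_param(Di, N, W, S) * scale
    di_in = Di * scale
    denom = 30.0 * a_in - 11.0 * di_in
    if denom <= 0:
        raise SpecValidationError(
            f"non-physical geometry: 30 A - 11 Di = {denom:.6g} <= 0"
        )
    return N**2 * a_in**2 / denom


def wheeler_inductance(spec: CoilSpec) -> float:
    """Flat-spiral inductance of a coil spec, microhenry (per lobe for a
    figure-8 topology)."""
    return wheeler_inductance_uH(
        spec.inner_diameter_mm,
        spec.turns,
        spec.wire_width_mm,
        spec.turn_gap_mm,
        unit="mm",
    )


def peak_field_estimate(
    spec: CoilSpec,
    radius_convention: RadiusConvention | str = RadiusConvention.inner_radius,
) -> float:
    """Centre flux-density estimate B = mu0 N I / (2 R) in tesla.

    R is selected by ``radius_convention``; the default inner-radius
    convention matches the design-stage estimate this model was built
    against.
    """
    conv = RadiusConvention(radius_convention)
    if conv is RadiusConvention.inner_radius:
        r_mm = spec.inner_diameter_mm / 2.0
    elif conv is RadiusConvention.outer_radius:
        do = spec.outer_diameter_mm or spec.effective_outer_diameter_mm
        r_mm = do / 2.0
    else:
        do = spec.outer_diameter_mm or spec.effective_outer_diameter_mm
        r_mm = (spec.inner_diameter_mm + do) / 4.0
    if r_mm <= 0:
        raise SpecValidationError("radius must be positive")
    return MU_0 * spec.turns * spec.current_A / (2.0 * r_mm * 1e-3)


def design_report(
    spec: CoilSpec,
    radius_convention: RadiusConvention | str = RadiusConvention.inner_radius,
) -> DesignEstimates:
    conv = RadiusConvention(radius_convention)
    return DesignEstimates(
        area_mm=coil_area(spec),
        inductance_uH=wheeler_inductance(spec),
        peak_field_T=peak_field_estimate(spec, conv),
        radius_convention=conv,
    )


_SPEC_KEYS = {
    "topology": "topology",
    "inner_diameter_mm": "inner_diameter_mm",
    "outer_diameter_mm": "outer_diameter_mm",
    "turns": "turns",
    "wire_width_mm": "wire_width_mm",
    "wire_height_mm": "wire_height_mm",
    "turn_gap_mm": "turn_gap_mm",
    "current_A": "current_A",
    "voltage_V": "voltage_V",
    "frequency_Hz": "frequency_Hz",
    "label": "label",
}


def spec_from_dict(d: Mapping[str, Any]) -> CoilSpec:
    """Build a CoilSpec from a config mapping (exact key names, units in
    the key names)."""
    unknown = set(d) - set(_SPEC_KEYS)
    if unknown:
        raise SpecValidationError(f"unknown coil config keys: {sorted(unknown)}")
    kwargs = {dst: d[src] for src, dst in _SPEC_KEYS.items() if src in d}
    return CoilSpec(**kwargs)


def spec_to_dict(spec: CoilSpec) -> dict[str, Any]:
    d = {
        "topology": spec.topology,
        "inner_diameter_mm": spec.inner_diameter_mm,
        "turns": spec.turns,
        "wire_width_mm": spec.wire_width_mm,
        "wire_height_mm": spec.wire_height_mm,
        "turn_gap_mm": spec.turn_gap_mm,
        "current_A": spec.current_A,
        "voltage_V": spec.voltage_V,
        "frequency_Hz": spec.frequency_Hz,
        "label": spec.label,
    }
    if spec.outer_diameter_mm is not None:
        d["outer_diameter_mm"] = spec.outer_diameter_mm
    return d


def default_mouse_coil(topology: str = "circular") -> CoilSpec:
    """The reference miniature coil design this package ships with:
    7-turn, 20 mm bore flat spiral of 3 x 2 mm wire driven at 1 kA peak."""
    return CoilSpec(
        topology=topology,
        inner_diameter_mm=20.0,
        turns=7,
        wire_width_mm=3.0,
        wire_height_mm=2.0,
        turn_gap_mm=0.2,
        current_A=1000.0,
        voltage_V=500.0,
        frequency_Hz=20.0,
        outer_diameter_mm=65.0,
        label="mouse_coil",
    )


def generic_human_coil() -> CoilSpec:
    """Stand-in for a clinical figure-8 device: two 70 mm lobes, 10 turns
    per lobe, 5 kA drive.  This is an explicitly generic surrogate, not the
    geometry of any particular commercial coil."""
    return CoilSpec(
        topology="figure8",
        inner_diameter_mm=50.0,
        turns=10,
        wire_width_mm=1.0,
        wire_height_mm=2.0,
        turn_gap_mm=0.0,
        current_A=5000.0,
        voltage_V=2000.0,
        frequency_Hz=20.0,
        label="human_coil_generic",
    )
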