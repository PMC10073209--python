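"""Lumped Joule-heating estimate for a winding.

Deliberately coarse: DC copper resistance of the total winding length, RMS
current from the pulse duty cycle, and a single convective film to ambient.
It reproduces orderings and scaling laws (more turns -> more heat, heating
quadratic in current) but makes no claim to match FEM temperature fields;
the convective coefficient and dissipation area defaults are uncalibrated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .coil import CoilSpec
from .constants import MM_TO_M, RHO_COPPER
from .fields import loop_centerline_radii_mm

__all__ = ["ThermalEstimate", "joule_power", "steady_temperature", "thermal_report"]

DEFAULT_AMBIENT_C = 25.0
DEFAULT_H_W_PER_M2K = 50.0  # forced-air film coefficient, uncalibrated default
DEFAULT_AREA_M2 = 0.01  # order-of-magnitude casing surface, uncalibrated


@dataclass(frozen=True)
class ThermalEstimate:
    mean_power_W: float
    steady_temperature_C: float
    ambient_C: float
    convective_coefficient_W_per_m2K: float
    dissipation_area_m2: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def winding_length_m(spec: CoilSpec) -> float:
    """Total conductor length: sum of centreline circumferences (both lobes
    for a figure-8)."""
    radii = loop_centerline_radii_mm(spec)
    length = float(2.0 * np.pi * radii.sum()) * MM_TO_M
    return 2.0 * length if spec.topology == "figure8" else length


def joule_power(spec: CoilSpec, duty: float) -> float:
    """Mean dissipated power P = (I sqrt(duty))^2 * R_dc in watts."""
    if not 0.0 < duty <= 1.0:
        raise ValueError("duty cycle must be in (0, 1]")
    cross_section_m2 = spec.wire_width_mm * spec.wire_height_mm * MM_TO_M**2
    if cross_section_m2 <= 0:
        raise ValueError("zero conductor cross-section")
    r_dc = RHO_COPPER * winding_length_m(spec) / cross_section_m2
    i_rms = spec.current_A * np.sqrt(duty)
    return float(i_rms**2 * r_dc)


def steady_temperature(
    power_W: float,
    convective_coefficient_W_per_m2K: float = DEFAULT_H_W_PER_M2K,
    area_m2: float = DEFAULT_AREA_M2,
    ambient_C: float = DEFAULT_AMBIENT_C,
) -> float:
    """Steady temperature of a lumped mass: ambient + P / (h A)."""
    if convective_coefficient_W_per_m2K <= 0:
        raise ValueError("convective coefficient must be > 0")
    if area_m2 <= 0:
        raise ValueError("dissipation area must be > 0")
    return ambient_C + power_W / (convective_coefficient_W_per_m2K * area_m2)


def thermal_report(
    spec: CoilSpec,
    duty: float,
    convective_coefficient_W_per_m2K: float = DEFAULT_H_W_PER_M2K,
    area_m2: float = DEFAULT_AREA_M2,
    ambient_C: float = DEFAULT_AMBIENT_C,
) -> ThermalEstimate:
    p = joule_power(spec, duty)
    return ThermalEstimate(
        mean_power_W=p,
        steady_temperature_C=steady_temperature(
            p, convective_coefficient_W_per_m2K, area_m2, ambient_C
        ),
        ambient_C=ambient_C,
        convective_coefficient_W_per_m2K=convective_coefficient_W_per_m2K,
        dissipation_area_m2=area_m2,
    )
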