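"""Layered head phantom and quasi-static induced electric field.

The phantom is an ordered outer-to-inner stack of tissue slabs (thickness,
relative permittivity, conductivity).  Under the quasi-static approximation
the tissue does not perturb the coil's magnetic field, and for an
axisymmetric winding the induced field is purely azimuthal:
E_phi = omega * A_phi, where A_phi is the magnetic vector potential of the
loop stack.  There is no scalar-potential term (axisymmetry means no charge
accumulation), so E is continuous across layer boundaries by construction.

The effective angular frequency omega stands in for the unknown spectral
content of the stimulator pulse; ``calibrate_drive`` recovers it from a
target E value at a stated depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.special import ellipe, ellipk

from .constants import MM_TO_M, MU_0, UM_TO_MM
from .fields import WindingModel

__all__ = [
    "TissueLayer",
    "HeadPhantom",
    "EFieldProfile",
    "build_phantom",
    "default_phantom",
    "vector_potential_phi",
    "induced_efield",
    "calibrate_drive",
    "phantom_from_records",
    "phantom_to_records",
]

#: Default murine tissue stack, outer to inner:
#: (name, thickness um, relative permittivity, conductivity S/m)
DEFAULT_TISSUES: tuple[tuple[str, float, float, float], ...] = (
    ("scalp", 500.0, 3056.0, 0.0009),
    ("skull", 1000.0, 1246.0, 0.0203),
    ("dura", 300.0, 2360.0, 0.5010),
    ("arachnoid", 75.0, 3013.0, 0.0650),
    ("brain", 890.0, 6683.0, 0.1056),
)


@dataclass(frozen=True)
class TissueLayer:
    name: str
    thickness_um: float
    rel_permittivity: float
    conductivity_S_per_m: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.conductivity_S_per_m < 0:
            raise ValueError(f"layer {self.name!r}: conductivity must be >= 0")
        if self.rel_permittivity < 1:
            raise ValueError(f"layer {self.name!r}: relative permittivity must be >= 1")


@dataclass(frozen=True)
class HeadPhantom:
    """Ordered outer-to-inner tissue stack with a coil-to-scalp standoff."""

    layers: tuple[TissueLayer, ...]
    standoff_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one tissue layer")
        if self.standoff_mm < 0:
            raise ValueError("standoff must be >= 0")

    @property
    def depth_to_inner_surface_mm(self) -> float:
        """Depth below the scalp surface of the innermost layer's outer
        boundary (the cortical surface for the default stack)."""
        return sum(l.thickness_um for l in self.layers[:-1]) * UM_TO_MM

    @property
    def total_depth_mm(self) -> float:
        return sum(l.thickness_um for l in self.layers) * UM_TO_MM

    def boundaries_mm(self) -> NDArray[np.float64]:
        """Depths of layer interfaces below the scalp surface, including 0
        and the bottom of the stack."""
        t = np.array([l.thickness_um for l in self.layers]) * UM_TO_MM
        return np.concatenate([[0.0], np.cumsum(t)])


@dataclass(frozen=True)
class EFieldProfile:
    depths_mm: NDArray[np.float64]
    e_V_per_m: NDArray[np.float64]
    omega_rad_per_s: float
    eval_radius_mm: NDArray[np.float64] = field(default=None)  # type: ignore[assignment]


def default_phantom(standoff_mm: float = 0.0) -> HeadPhantom:
    """Five-layer murine stack (scalp, skull, dura, arachnoid, brain)."""
    return HeadPhantom(
        tuple(TissueLayer(*row) for row in DEFAULT_TISSUES), standoff_mm
    )


def build_phantom(
    layers: Iterable[TissueLayer | tuple | Mapping[str, Any]],
    standoff_mm: float = 0.0,
) -> HeadPhantom:
    """Assemble a phantom from layer records ordered outer to inner."""
    built: list[TissueLayer] = []
    for row in layers:
        if isinstance(row, TissueLayer):
            built.append(row)
        elif isinstance(row, Mapping):
            built.append(
                TissueLayer(
                    name=row["tissue"],
                    thickness_um=float(row["thickness_um"]),
                    rel_permittivity=float(row["permittivity"]),
                    conductivity_S_per_m=float(row["conductivity_S_per_m"]),
                )
            )
        else:
            built.append(TissueLayer(*row))
    return HeadPhantom(tuple(built), standoff_mm)


def phantom_from_records(records: Sequence[Mapping[str, Any]], standoff_mm: float = 0.0) -> HeadPhantom:
    return build_phantom(records, standoff_mm)


def phantom_to_records(phantom: HeadPhantom) -> list[dict[str, Any]]:
    return [
        {
            "tissue": l.name,
            "thickness_um": l.thickness_um,
            "permittivity": l.rel_permittivity,
            "conductivity_S_per_m": l.conductivity_S_per_m,
        }
        for l in phantom.layers
    ]


def _loop_a_phi(a_m: float, current_A: float, rho_m: NDArray, z_m: NDArray) -> NDArray:
    """Azimuthal vector potential of one loop, SI (T*m).

    Elliptic-integral closed form; small rho handled by the leading-order
    dipole expression to avoid the 0/0 at the axis.
    """
    rho = np.asarray(rho_m, dtype=float)
    z = np.asarray(z_m, dtype=float)
    a_phi = np.zeros_like(rho)
    near_axis = rho < 1e-9 * max(a_m, 1e-9)
    off = ~near_axis
    if np.any(near_axis):
        zn = z[near_axis]
        a_phi[near_axis] = (
            MU_0 * current_A * a_m**2 * rho[near_axis] / (4.0 * (a_m**2 + zn**2) ** 1.5)
        )
    if np.any(off):
        r, zz = rho[off], z[off]
        m = 4.0 * a_m * r / ((a_m + r) ** 2 + zz**2)
        k = np.sqrt(m)
        a_phi[off] = (
            MU_0
            * current_A
            / (np.pi * k)
            * np.sqrt(a_m / r)
            * ((1.0 - m / 2.0) * ellipk(m) - ellipe(m))
        )
    return a_phi


def vector_potential_phi(
    winding: WindingModel, rho_mm: NDArray, z_mm: NDArray
) -> NDArray[np.float64]:
    """A_phi (T*m) of a circular winding at cylindrical points (rho, z) in mm.

    Requires the circular topology (all loops concentric about the z axis).
    """
    if winding.topology != "circular":
        raise ValueError(
            "vector-potential route supports axisymmetric (circular) windings "
            "only; use the field-map based variant for figure-8 coils"
        )
    rho = np.atleast_1d(np.asarray(rho_mm, dtype=float)) * MM_TO_M
    z = np.atleast_1d(np.asarray(z_mm, dtype=float)) * MM_TO_M
    total = np.zeros_like(rho)
    for loop in winding.loops:
        total += _loop_a_phi(loop.radius_mm * MM_TO_M, loop.current_A, rho, z)
    return total


def _max_a_phi_at_depth(
    winding: WindingModel, z_mm: float, n_rho: int = 400
) -> tuple[float, float]:
    """(max |A_phi|, argmax radius mm) over a radial scan at height z."""
    r_outer = max(lp.radius_mm for lp in winding.loops)
    rho = np.linspace(0.05, r_outer + 20.0, n_rho)
    a = np.abs(vector_potential_phi(winding, rho, np.full_like(rho, z_mm)))
    i = int(np.argmax(a))
    return float(a[i]), float(rho[i])


def induced_efield(
    winding: WindingModel,
    phantom: HeadPhantom,
    omega_rad_per_s: float,
    points_per_layer: int = 9,
) -> EFieldProfile:
    """Induced |E| down through the layer stack.

    At each depth the magnitude is reported on the ring of maximal |A_phi|
    (the hottest azimuthal circle); E = omega * |A_phi| there.  With
    omega = 0 the profile is identically zero.
    """
    if omega_rad_per_s < 0:
        raise ValueError("omega must be >= 0")
    bounds = phantom.boundaries_mm()
    depths: list[float] = []
    for d0, d1 in zip(bounds[:-1], bounds[1:]):
        depths.extend(np.linspace(d0, d1, points_per_layer, endpoint=False))
    depths.append(float(bounds[-1]))
    depths_arr = np.array(depths)
    e_vals = np.empty_like(depths_arr)
    radii = np.empty_like(depths_arr)
    for i, depth in enumerate(depths_arr):
        a_max, rho_star = _max_a_phi_at_depth(winding, phantom.standoff_mm + depth)
        e_vals[i] = omega_rad_per_s * a_max
        radii[i] = rho_star
    return EFieldProfile(depths_arr, e_vals, float(omega_rad_per_s), radii)


def efield_at_depth(
    winding: WindingModel,
    phantom: HeadPhantom,
    omega_rad_per_s: float,
    depth_mm: float,
) -> float:
    """|E| (V/m) on the max-|A_phi| ring at one depth below the scalp."""
    a_max, _ = _max_a_phi_at_depth(winding, phantom.standoff_mm + depth_mm)
    return omega_rad_per_s * a_max


def calibrate_drive(
    winding: WindingModel,
    phantom: HeadPhantom,
    target_e_V_per_m: float,
    depth_mm: float | None = None,
) -> float:
    """Effective angular frequency reproducing ``target_e`` at ``depth``.

    Closed form: omega = target / max_rho |A_phi| at that depth.  The depth
    defaults to the inner (cortical) surface of the phantom.
    """
    if target_e_V_per_m <= 0:
        raise ValueError("target E must be > 0")
    if depth_mm is None:
        depth_mm = phantom.depth_to_inner_surface_mm
    a_max, _ = _max_a_phi_at_depth(winding, phantom.standoff_mm + depth_mm)
    if a_max == 0.0:
        raise ValueError("vector potential vanishes at the requested depth")
    return target_e_V_per_m / a_max
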