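"""Synthetic gaussmeter readings for the validation experiment.

Replicate flux-density readings per device and coil-to-head distance are
drawn as truth * (1 + relative Gaussian noise) + absolute Gaussian noise,
reproducibly from a seed.  Truth values come from the field solver,
evaluated at the cortical-surface depth below the plane the coil sits at.

Devices: ``mouse_coil`` (miniature spiral measured in air), ``human_coil``
(a generic 70 mm figure-8 surrogate for a clinical device), ``simulation``
(noise-free model prediction) and ``measurement`` (the in vivo stand-in,
noisy readings around the mouse-coil truth).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.typing import NDArray

from .coil import default_mouse_coil, generic_human_coil
from .fields import WindingModel, build_winding, field_map_on_plane

__all__ = [
    "NoiseModel",
    "MeasurementSet",
    "simulate_readings",
    "winding_truth",
    "mouse_coil_truth",
    "human_coil_truth",
    "generate_panel",
    "DEVICES",
    "DEFAULT_DISTANCES_MM",
]

DEVICES = ("human_coil", "mouse_coil", "simulation", "measurement")
DEFAULT_DISTANCES_MM = (0.0, 2.0, 5.0, 8.0)

#: Depth of the cortical surface below the scalp for the default phantom.
CORTICAL_DEPTH_MM = 1.875


@dataclass(frozen=True)
class NoiseModel:
    relative_sd: float = 0.05
    absolute_sd_T: float = 1e-3

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.absolute_sd_T < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class MeasurementSet:
    device: str
    distance_mm: float
    readings_T: NDArray[np.float64]
    noise_model: NoiseModel
    seed: int

    def __post_init__(self) -> None:
        if len(self.readings_T) < 2:
            raise ValueError("a measurement set needs at least 2 replicates")
        if not np.all(np.isfinite(self.readings_T)):
            raise ValueError("readings must be finite")

    @property
    def n(self) -> int:
        return len(self.readings_T)


def simulate_readings(
    truth_T: float,
    noise_model: NoiseModel,
    n: int,
    seed: int,
    device: str = "measurement",
    distance_mm: float = 0.0,
) -> MeasurementSet:
    """Draw n replicate readings around a truth value, reproducibly."""
    if truth_T < 0:
        raise ValueError("truth must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    rng = np.random.default_rng(seed)
    rel = rng.normal(0.0, 1.0, size=n) * noise_model.relative_sd
    absn = rng.normal(0.0, 1.0, size=n) * noise_model.absolute_sd_T
    readings = truth_T * (1.0 + rel) + absn
    return MeasurementSet(device, float(distance_mm), readings, noise_model, seed)


def winding_truth(
    winding: WindingModel,
    distance_mm: float,
    depth_offset_mm: float = CORTICAL_DEPTH_MM,
    extent_mm: float | tuple[float, float] = 90.0,
    spacing_mm: float = 1.5,
) -> float:
    """Model-predicted reading: peak |B| on the plane one cortical depth
    below the coil-to-scalp gap."""
    fmap = field_map_on_plane(
        winding, distance_mm + depth_offset_mm, extent_mm, spacing_mm
    )
    return float(fmap.b_T.max())


@lru_cache(maxsize=64)
def mouse_coil_truth(distance_mm: float) -> float:
    return winding_truth(build_winding(default_mouse_coil()), distance_mm)


@lru_cache(maxsize=64)
def human_coil_truth(distance_mm: float) -> float:
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    return winding_truth(
        build_winding(generic_human_coil()),
        distance_mm,
        extent_mm=(180.0, 100.0),
        spacing_mm=2.0,
    )


def generate_panel(
    distances_mm: tuple[float, ...] = DEFAULT_DISTANCES_MM,
    n: int = 5,
    seed: int = 0,
    noise_model: NoiseModel | None = None,
) -> list[MeasurementSet]:
    """Full synthetic panel: one MeasurementSet per device per distance.

    The ``simulation`` group carries the noise-free model prediction
    replicated n times; the other three devices get independent noisy draws.
    Child seeds are spawned deterministically from ``seed``.
    """
    noise = noise_model or NoiseModel()
    no_noise = NoiseModel(0.0, 0.0)
    sets: list[MeasurementSet] = []
    counter = 0
    for d in distances_mm:
        truths = {
            "human_coil": human_coil_truth(d),
            "mouse_coil": mouse_coil_truth(d),
            "simulation": mouse_coil_truth(d),
            "measurement": mouse_coil_truth(d),
        }
        for device in DEVICES:
            child_seed = int(
                np.random.SeedSequence([int(seed), counter]).generate_state(1)[0]
            )
            nm = no_noise if device == "simulation" else noise
            sets.append(
                simulate_readings(truths[device], nm, n, child_seed, device, d)
            )
            counter += 1
    return sets
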