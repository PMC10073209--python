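"""Config-file loading and output helpers shared by the CLI and pipeline.

Configs are YAML with flat, unit-suffixed key names (lengths mm, currents A,
fields T).  Every CSV written by the package starts with comment-line
metadata (tool version, config hash, seed) so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .coil import CoilSpec, spec_from_dict, spec_to_dict
from .phantom import HeadPhantom, phantom_from_records, phantom_to_records
from .synthetic import DEFAULT_DISTANCES_MM, NoiseModel

__all__ = [
    "PipelineConfig",
    "load_coil_config",
    "save_coil_config",
    "load_phantom_config",
    "save_phantom_config",
    "load_pipeline_config",
    "config_hash",
    "metadata_header",
    "write_csv_with_metadata",
]


def load_coil_config(path: str | Path) -> CoilSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"coil config {path} must be a mapping")
    return spec_from_dict(data)


def save_coil_config(spec: CoilSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_phantom_config(path: str | Path) -> HeadPhantom:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, Mapping):
        layers = data["layers"]
        standoff = float(data.get("standoff_mm", 0.0))
    else:
        layers, standoff = data, 0.0
    return phantom_from_records(layers, standoff)


def save_phantom_config(phantom: HeadPhantom, path: str | Path) -> None:
    doc = {"standoff_mm": phantom.standoff_mm, "layers": phantom_to_records(phantom)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass(frozen=True)
class PipelineConfig:
    coil: CoilSpec
    comparison_coil: CoilSpec | None = None
    phantom: HeadPhantom | None = None
    distances_mm: tuple[float, ...] = DEFAULT_DISTANCES_MM
    sweep_distances_mm: tuple[float, ...] = (0.0, 2.0, 5.0, 8.0, 10.0)
    plane_distance_mm: float = 5.0
    extent_mm: float = 100.0
    spacing_mm: float = 1.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    replicates: int = 5
    seed: int = 0
    target_e_V_per_m: float = 136.1452
    output_dir: Path = Path("minitms_out")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "coil": spec_to_dict(self.coil),
            "distances_mm": list(self.distances_mm),
            "sweep_distances_mm": list(self.sweep_distances_mm),
            "plane_distance_mm": self.plane_distance_mm,
            "extent_mm": self.extent_mm,
            "spacing_mm": self.spacing_mm,
            "noise": {
                "relative_sd": self.noise_model.relative_sd,
                "absolute_sd_T": self.noise_model.absolute_sd_T,
            },
            "replicates": self.replicates,
            "seed": self.seed,
            "target_e_V_per_m": self.target_e_V_per_m,
        }
        if self.comparison_coil is not None:
            d["comparison_coil"] = spec_to_dict(self.comparison_coil)
        if self.phantom is not None:
            d["phantom"] = phantom_to_records(self.phantom)
            d["standoff_mm"] = self.phantom.standoff_mm
        return d


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kwargs: dict[str, Any] = {}
    kwargs["coil"] = spec_from_dict(data["coil"])
    if "comparison_coil" in data:
        kwargs["comparison_coil"] = spec_from_dict(data["comparison_coil"])
    if "phantom" in data:
        kwargs["phantom"] = phantom_from_records(
            data["phantom"], float(data.get("standoff_mm", 0.0))
        )
    for key in (
        "plane_distance_mm",
        "extent_mm",
        "spacing_mm",
        "replicates",
        "seed",
        "target_e_V_per_m",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "distances_mm" in data:
        kwargs["distances_mm"] = tuple(float(x) for x in data["distances_mm"])
    if "sweep_distances_mm" in data:
        kwargs["sweep_distances_mm"] = tuple(float(x) for x in data["sweep_distances_mm"])
    if "noise" in data:
        kwargs["noise_model"] = NoiseModel(
            relative_sd=float(data["noise"].get("relative_sd", 0.05)),
            absolute_sd_T=float(data["noise"].get("absolute_sd_T", 1e-3)),
        )
    if "output_dir" in data:
        kwargs["output_dir"] = Path(data["output_dir"])
    return PipelineConfig(**kwargs)


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serializable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(seed: int | None, cfg_hash: str) -> str:
    lines = [f"# minitms v{__version__}", f"# config_hash={cfg_hash}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def write_csv_with_metadata(
    path: str | Path,
    columns: Sequence[str],
    rows: Sequence[Sequence[Any]],
    seed: int | None,
    cfg_hash: str,
) -> None:
    out = [metadata_header(seed, cfg_hash).rstrip("\n"), ",".join(columns)]
    for row in rows:
        out.append(",".join(repr(v) if isinstance(v, float) else str(v) for v in row))
    Path(path).write_text("\n".join(out) + "\n")
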