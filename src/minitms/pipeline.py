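"""End-to-end workflow: design report, field maps and focality comparison,
distance sweep, phantom E-field calibration, synthetic measurement panel and
the statistics stage, with every artifact written to an output directory and
a single summary JSON of the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

from .coil import CoilSpec, default_mouse_coil, design_report
from .config import (
    PipelineConfig,
    config_hash,
    write_csv_with_metadata,
)
from .fields import (
    FieldMap,
    build_winding,
    compare_coil_focality,
    distance_sweep,
    field_map_on_plane,
    focality_metrics,
)
from .phantom import calibrate_drive, default_phantom, induced_efield
from .stats import distance_panel
from .synthetic import generate_panel
from .thermal import thermal_report

__all__ = ["run_pipeline", "default_pipeline_config"]

log = logging.getLogger(__name__)


def default_pipeline_config(output_dir: str | Path = "minitms_out", seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        coil=default_mouse_coil(),
        comparison_coil=default_mouse_coil(topology="figure8"),
        phantom=default_phantom(),
        seed=seed,
        output_dir=Path(output_dir),
    )


def _write_field_map(fmap: FieldMap, path: Path, seed: int, cfg_hash: str) -> None:
    rows = []
    for iy, yv in enumerate(fmap.y_mm):
        for ix, xv in enumerate(fmap.x_mm):
            rows.append((float(xv), float(yv), float(fmap.b_T[iy, ix])))
    write_csv_with_metadata(path, ("x_mm", "y_mm", "B_T"), rows, seed, cfg_hash)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the summary dict (also written to
    summary.json in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.to_dict())
    seed = config.seed
    summary: dict[str, Any] = {
        "config_hash": cfg_hash,
        "seed": seed,
        "coil_label": config.coil.label,
    }

    # --- design ---
    design = _stage("design")(design_report)(config.coil)
    (out / "design.json").write_text(design.to_json())
    summary["area_mm"] = design.area_mm
    summary["inductance_uH"] = design.inductance_uH
    summary["peak_field_T"] = design.peak_field_T

    winding = _stage("winding")(build_winding)(config.coil)

    # --- field map + focality for the primary coil ---
    fmap = _stage("field_map")(field_map_on_plane)(
        winding, config.plane_distance_mm, config.extent_mm, config.spacing_mm
    )
    _write_field_map(fmap, out / f"map_{config.coil.topology}.csv", seed, cfg_hash)
    foc = _stage("focality")(focality_metrics)(fmap)
    summary["peak_count"] = foc.peak_count
    summary["fwhm_area_mm2"] = foc.fwhm_area_mm2

    # --- circular vs figure-8 comparison (voltage-matched drive) ---
    if config.comparison_coil is not None:
        cmp_reports = _stage("comparison")(compare_coil_focality)(
            config.coil if config.coil.topology == "circular" else config.comparison_coil,
            distance_mm=config.plane_distance_mm,
            spacing_mm=config.spacing_mm,
            extent_mm=config.extent_mm,
        )
        summary["comparison"] = {
            topo: {
                "peak_count": r.peak_count,
                "fwhm_area_mm2": r.fwhm_area_mm2,
                "peak_value_T": r.peak_value_T,
            }
            for topo, r in cmp_reports.items()
        }
        summary["comparison"]["circular_more_focal"] = (
            cmp_reports["circular"].fwhm_area_mm2
            < cmp_reports["figure8"].fwhm_area_mm2
        )
        (out / "focality_comparison.json").write_text(
            json.dumps(summary["comparison"], indent=2)
        )

    # --- distance sweep ---
    sweep = _stage("sweep")(distance_sweep)(
        winding, config.sweep_distances_mm, config.extent_mm, config.spacing_mm
    )
    write_csv_with_metadata(
        out / "sweep.csv",
        ("distance_mm", "peak_B_T"),
        list(zip(sweep.distances_mm, sweep.peak_B_T)),
        seed,
        cfg_hash,
    )
    summary["sweep_peak_B_T"] = dict(zip(map(str, sweep.distances_mm), sweep.peak_B_T))

    # --- phantom E-field (circular primary only) ---
    phantom = config.phantom or default_phantom()
    if config.coil.topology == "circular":
        omega = _stage("calibrate")(calibrate_drive)(
            winding, phantom, config.target_e_V_per_m
        )
        profile = _stage("efield")(induced_efield)(winding, phantom, omega)
        write_csv_with_metadata(
            out / "efield_profile.csv",
            ("depth_mm", "E_V_per_m"),
            list(zip(profile.depths_mm.tolist(), profile.e_V_per_m.tolist())),
            seed,
            cfg_hash,
        )
        summary["omega_rad_per_s"] = omega
        summary["effective_frequency_kHz"] = omega / (2.0 * 3.141592653589793) / 1e3
        summary["e_cortex_V_per_m"] = float(
            profile.e_V_per_m[
                abs(profile.depths_mm - phantom.depth_to_inner_surface_mm).argmin()
            ]
        )

    # --- thermal ---
    therm = _stage("thermal")(thermal_report)(config.coil, duty=0.01)
    (out / "thermal.json").write_text(therm.to_json())
    summary["mean_power_W"] = therm.mean_power_W

    # --- synthetic measurements + statistics ---
    sets = _stage("synthetic")(generate_panel)(
        config.distances_mm, config.replicates, seed, config.noise_model
    )
    rows = []
    for s in sets:
        for i, r in enumerate(s.readings_T):
            rows.append((s.device, s.distance_mm, i, float(r)))
    write_csv_with_metadata(
        out / "measurements.csv",
        ("device", "distance_mm", "replicate", "reading_T"),
        rows,
        seed,
        cfg_hash,
    )
    panel = _stage("stats")(distance_panel)(sets, config.distances_mm)
    stats_doc = {
        str(d): {name: res.to_dict() for name, res in comps.items()}
        for d, comps in panel.items()
    }
    (out / "stats_panel.json").write_text(json.dumps(stats_doc, indent=2))
    summary["p_values"] = {
        str(d): {
            "human_vs_mouse": comps["human_vs_mouse"].p_value,
            "simulation_vs_measurement": comps["simulation_vs_measurement"].p_value,
        }
        for d, comps in panel.items()
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    log.info("pipeline finished; outputs in %s", out)
    return summary
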