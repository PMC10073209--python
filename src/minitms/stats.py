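"""One-way fixed-effects ANOVA comparing measurement groups, plus the
per-distance comparison panel used for simulation-versus-measurement
validation.

The F statistic is computed from sums of squares directly (not delegated to
a library routine) so the degenerate all-identical case can be defined as
F = 0, p = 1 instead of NaN; tests cross-check against scipy's ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import stats as sps

from .synthetic import MeasurementSet

__all__ = ["ComparisonResult", "one_way_anova", "distance_panel", "ALPHA"]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    f_statistic: float
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_labels),
            "means": list(self.group_means),
            "sems": list(self.group_sems),
            "F": self.f_statistic,
            "p": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
        }


def _as_arrays(
    groups: Sequence[MeasurementSet | NDArray | Sequence[float]],
) -> tuple[list[NDArray[np.float64]], list[str]]:
    arrays: list[NDArray[np.float64]] = []
    labels: list[str] = []
    for i, g in enumerate(groups):
        if isinstance(g, MeasurementSet):
            arrays.append(np.asarray(g.readings_T, dtype=float))
            labels.append(g.device)
        else:
            arrays.append(np.asarray(g, dtype=float))
            labels.append(f"group{i}")
    return arrays, labels


def one_way_anova(
    groups: Sequence[MeasurementSet | NDArray | Sequence[float]],
    labels: Sequence[str] | None = None,
) -> ComparisonResult:
    """Classical one-way ANOVA across two or more groups.

    Degenerate cases: all readings identical everywhere -> F = 0, p = 1;
    zero within-group variance with distinct means -> F = inf, p = 0.
    """
    arrays, auto_labels = _as_arrays(groups)
    if labels is not None:
        auto_labels = list(labels)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for lab, arr in zip(auto_labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} needs at least 2 readings")

    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n_total = len(all_vals)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k

    if ss_within <= 0.0:
        if np.isclose(ss_between, 0.0):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f_stat, df_between, df_within))

    means = tuple(float(a.mean()) for a in arrays)
    sems = tuple(
        float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0 for a in arrays
    )
    return ComparisonResult(tuple(auto_labels), means, sems, float(f_stat), float(p))


def distance_panel(
    sets: Iterable[MeasurementSet],
    distances_mm: Sequence[float],
    required_devices: Sequence[str] = ("human_coil", "mouse_coil", "simulation", "measurement"),
) -> dict[float, Mapping[str, ComparisonResult]]:
    """Per-distance comparisons over the four validation groups.

    For each distance: the omnibus ANOVA across all groups, the pairwise
    human-versus-mouse contrast and the pairwise simulation-versus-
    measurement contrast (two-group ANOVA, no multiplicity correction).
    """
    by_key: dict[tuple[float, str], MeasurementSet] = {}
    for s in sets:
        by_key[(s.distance_mm, s.device)] = s
    panel: dict[float, Mapping[str, ComparisonResult]] = {}
    for d in distances_mm:
        d = float(d)
        missing = [dev for dev in required_devices if (d, dev) not in by_key]
        if missing:
            raise ValueError(
                f"distance {d} mm is missing measurement group(s): {missing}"
            )
        groups = [by_key[(d, dev)] for dev in required_devices]
        panel[d] = {
            "omnibus": one_way_anova(groups),
            "human_vs_mouse": one_way_anova(
                [by_key[(d, "human_coil")], by_key[(d, "mouse_coil")]]
            ),
            "simulation_vs_measurement": one_way_anova(
                [by_key[(d, "simulation")], by_key[(d, "measurement")]]
            ),
        }
    return panel
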