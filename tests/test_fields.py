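import dataclasses

import numpy as np
import pytest

from minitms.coil import CoilSpec, default_mouse_coil
from minitms.constants import MU_0
from minitms.fields import (
    FieldMap,
    Loop,
    WindingModel,
    bfield_at_points,
    build_winding,
    compare_coil_focality,
    distance_sweep,
    field_map_on_plane,
    focality_metrics,
    loop_centerline_radii_mm,
    neumann_self_inductance,
)

from conftest import segment_biot_savart

ZHAT = np.array([0.0, 0.0, 1.0])


def single_loop_winding(radius_mm=10.0, current_A=1000.0, wire_radius_mm=1.1175):
    spec = default_mouse_coil()
    loop = Loop(np.zeros(3), radius_mm, ZHAT, current_A)
    return WindingModel((loop,), spec, wire_radius_mm)


class TestBuildWinding:
    def test_circular_centerline_radii(self, mouse_winding):
        radii = [lp.radius_mm for lp in mouse_winding.loops]
        assert radii == pytest.approx([11.5, 14.7, 17.9, 21.1, 24.3, 27.5, 30.7])

    def test_circular_ampere_turns(self, mouse_spec, mouse_winding):
        total = sum(lp.current_A for lp in mouse_winding.loops)
        assert total == pytest.approx(mouse_spec.turns * mouse_spec.current_A)

    def test_figure8_two_lobes_opposite_currents(self, fig8_winding):
        assert len(fig8_winding.loops) == 14
        currents = np.array([lp.current_A for lp in fig8_winding.loops])
        assert np.all(currents[:7] == 1000.0) and np.all(currents[7:] == -1000.0)
        xs = np.array([lp.center_mm[0] for lp in fig8_winding.loops])
        # lobe centre separation equals one lobe outer diameter (tangent lobes)
        lobe_outer = 30.7 + 1.5
        assert xs[0] == pytest.approx(-lobe_outer)
        assert xs[-1] == pytest.approx(lobe_outer)

    def test_equivalent_wire_radius_gmd(self, mouse_winding):
        assert mouse_winding.equivalent_wire_radius_mm == pytest.approx(
            0.2235 * (3.0 + 2.0)
        )


class TestBfield:
    def test_single_loop_center_closed_form(self):
        # B = mu0 I / (2a) at the loop centre
        w = single_loop_winding(radius_mm=10.0, current_A=1000.0)
        b = bfield_at_points(w, [[0.0, 0.0, 0.0]])[0]
        assert np.linalg.norm(b) == pytest.approx(MU_0 * 1000.0 / 0.02, rel=1e-12)
        assert b[0] == b[1] == 0.0

    def test_on_axis_at_z_equals_a(self):
        w = single_loop_winding(radius_mm=10.0)
        b0 = bfield_at_points(w, [[0.0, 0.0, 0.0]])[0, 2]
        bz = bfield_at_points(w, [[0.0, 0.0, 10.0]])[0, 2]
        assert bz == pytest.approx(b0 * 2 ** (-1.5), rel=1e-12)

    def test_zero_current_zero_field(self):
        w = single_loop_winding(current_A=0.0)
        b = bfield_at_points(w, np.random.default_rng(0).normal(size=(10, 3)) * 30)
        assert np.all(b == 0.0)

    def test_elliptic_matches_segment_discretization(self):
        # independent oracle: 1024-segment polygonal Biot-Savart
        w = single_loop_winding(radius_mm=15.0, current_A=1000.0, wire_radius_mm=0.5)
        rng = np.random.default_rng(7)
        pts = rng.uniform(-40, 40, size=(40, 3))
        rho = np.hypot(pts[:, 0], pts[:, 1])
        far = np.hypot(rho - 15.0, pts[:, 2]) > 2 * 0.5
        pts = pts[far]
        b_exact = bfield_at_points(w, pts)
        b_seg = segment_biot_savart(15.0, 1000.0, pts, n_segments=1024)
        err = np.linalg.norm(b_exact - b_seg, axis=1) / np.linalg.norm(b_seg, axis=1)
        assert np.max(err) < 1e-4

    def test_superposition_of_figure8_lobes(self, fig8_winding):
        spec = fig8_winding.source_spec
        left = WindingModel(
            fig8_winding.loops[:7], spec, fig8_winding.equivalent_wire_radius_mm
        )
        right = WindingModel(
            fig8_winding.loops[7:], spec, fig8_winding.equivalent_wire_radius_mm
        )
        pts = np.random.default_rng(3).uniform(-60, 60, size=(25, 3))
        total = bfield_at_points(fig8_winding, pts)
        parts = bfield_at_points(left, pts) + bfield_at_points(right, pts)
        np.testing.assert_allclose(total, parts, rtol=0, atol=1e-15)

    def test_near_wire_clamp_keeps_field_finite(self, mouse_winding):
        on_wire = [[11.5, 0.0, 0.0]]
        b = bfield_at_points(mouse_winding, on_wire)
        assert np.all(np.isfinite(b))
        # clamped to the wire surface: of the order of mu0 I / (2 pi r_w)
        approx_surface = MU_0 * 1000.0 / (2 * np.pi * 1.1175e-3)
        assert np.linalg.norm(b) < 10 * approx_surface

    def test_bad_point_shape_rejected(self, mouse_winding):
        with pytest.raises(ValueError, match="shape"):
            bfield_at_points(mouse_winding, [[1.0, 2.0]])


class TestFieldMap:
    def test_circular_map_axisymmetric(self, mouse_winding):
        fmap = field_map_on_plane(mouse_winding, 5.0, 60.0, 2.0)
        b = fmap.b_T
        np.testing.assert_allclose(b, b[::-1, :], rtol=1e-9)
        np.testing.assert_allclose(b, b[:, ::-1], rtol=1e-9)

    def test_single_focus_for_circular(self, mouse_winding):
        fmap = field_map_on_plane(mouse_winding, 5.0, 100.0, 1.0)
        assert focality_metrics(fmap).peak_count == 1

    def test_two_foci_for_figure8(self, fig8_winding):
        fmap = field_map_on_plane(fig8_winding, 5.0, (160.0, 100.0), 1.0)
        assert focality_metrics(fmap).peak_count == 2

    def test_empty_grid_rejected(self, mouse_winding):
        with pytest.raises(ValueError, match="spacing"):
            field_map_on_plane(mouse_winding, 5.0, 100.0, 0.0)
        with pytest.raises(ValueError, match="distance"):
            field_map_on_plane(mouse_winding, -1.0, 100.0, 1.0)


class TestDistanceSweep:
    def test_monotone_decreasing(self, mouse_winding):
        sweep = distance_sweep(mouse_winding, [0, 2, 5, 8, 10], 100.0, 1.0)
        assert all(
            a > b for a, b in zip(sweep.peak_B_T, sweep.peak_B_T[1:])
        )

    def test_decay_ratio_matches_reference_trend(self, mouse_winding):
        sweep = distance_sweep(mouse_winding, [0, 10], 100.0, 1.0)
        ratio = sweep.peak_B_T[1] / sweep.peak_B_T[0]
        assert 0.20 < ratio < 0.40

    def test_far_field_dipole_slope(self, mouse_winding):
        sweep = distance_sweep(mouse_winding, [200.0, 400.0], 40.0, 2.0)
        slope = np.log(sweep.peak_B_T[1] / sweep.peak_B_T[0]) / np.log(2.0)
        assert slope == pytest.approx(-3.0, abs=0.1)

    def test_zero_current_all_zero(self):
        loops = tuple(
            Loop(np.zeros(3), r, ZHAT, 0.0) for r in (10.0, 13.0)
        )
        w = WindingModel(loops, default_mouse_coil(), 1.0)
        sweep = distance_sweep(w, [1.0, 5.0], 40.0, 2.0)
        assert sweep.peak_B_T == (0.0, 0.0)

    def test_unsorted_distances_rejected(self, mouse_winding):
        with pytest.raises(ValueError, match="ascending"):
            distance_sweep(mouse_winding, [5.0, 2.0], 40.0, 2.0)


class TestNeumannInductance:
    def test_reference_winding_near_fem_value(self, mouse_winding):
        L = neumann_self_inductance(mouse_winding)
        assert abs(L - 1.956066) / 1.956066 < 0.15

    def test_agrees_with_flat_spiral_formula(self, mouse_spec, mouse_winding):
        from minitms.coil import wheeler_inductance

        L_n = neumann_self_inductance(mouse_winding)
        L_w = wheeler_inductance(mouse_spec)
        assert abs(L_n - L_w) / L_w < 0.15

    def test_single_loop_reduces_to_self_term(self):
        w = single_loop_winding(radius_mm=10.0, wire_radius_mm=1.1175)
        expected = MU_0 * 0.010 * (np.log(8 * 0.010 / 1.1175e-3) - 2.0) * 1e6
        assert neumann_self_inductance(w) == pytest.approx(expected, rel=1e-12)

    def test_length_scaling_law(self, mouse_spec, mouse_winding):
        scaled_spec = CoilSpec(
            inner_diameter_mm=40.0,
            turns=7,
            wire_width_mm=6.0,
            wire_height_mm=4.0,
            turn_gap_mm=0.4,
        )
        L1 = neumann_self_inductance(mouse_winding)
        L2 = neumann_self_inductance(build_winding(scaled_spec))
        assert L2 / L1 == pytest.approx(2.0, rel=0.05)

    def test_overlapping_loops_rejected(self):
        loops = tuple(Loop(np.zeros(3), 10.0, ZHAT, 1.0) for _ in range(2))
        w = WindingModel(loops, default_mouse_coil(), 1.0)
        with pytest.raises(ValueError, match="overlapping"):
            neumann_self_inductance(w)

    def test_figure8_not_supported(self, fig8_winding):
        with pytest.raises(ValueError, match="circular"):
            neumann_self_inductance(fig8_winding)


class TestFocality:
    def test_comparison_booleans(self):
        reports = compare_coil_focality(default_mouse_coil(), spacing_mm=1.0)
        circ, fig8 = reports["circular"], reports["figure8"]
        assert circ.peak_count == 1
        assert fig8.peak_count == 2
        assert circ.fwhm_area_mm2 < fig8.fwhm_area_mm2
        assert circ.peak_value_T > fig8.peak_value_T

    def test_constant_map_rejected(self):
        fmap = FieldMap(5.0, np.arange(5.0), np.arange(5.0), np.ones((5, 5)), 1.0)
        with pytest.raises(ValueError, match="constant"):
            focality_metrics(fmap)

    def test_zero_map_rejected(self):
        fmap = FieldMap(5.0, np.arange(5.0), np.arange(5.0), np.zeros((5, 5)), 1.0)
        with pytest.raises(ValueError, match="zero"):
            focality_metrics(fmap)

    def test_scale_invariance(self, mouse_winding):
        fmap = field_map_on_plane(mouse_winding, 5.0, 80.0, 2.0)
        scaled = dataclasses.replace(fmap, b_T=37.5 * fmap.b_T)
        r1, r2 = focality_metrics(fmap), focality_metrics(scaled)
        assert r1.peak_count == r2.peak_count
        assert r1.fwhm_area_mm2 == r2.fwhm_area_mm2

    def test_two_gaussians_counted(self):
        x = np.linspace(-10, 10, 81)
        X, Y = np.meshgrid(x, x)
        b = np.exp(-((X - 5) ** 2 + Y**2) / 4) + 0.9 * np.exp(
            -((X + 5) ** 2 + Y**2) / 4
        )
        fmap = FieldMap(0.0, x, x, b, float(x[1] - x[0]))
        assert focality_metrics(fmap).peak_count == 2
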