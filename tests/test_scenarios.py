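"""Scenario presets and vessel rasterization."""

import numpy as np
import pytest

import fustherm as ft
from fustherm.scenarios import MULTI_PAIR_LAYOUT


class TestPresets:
    def test_large_artery_parameters(self):
        sc = ft.make_scenario("large_artery")
        (v,) = sc.vessels
        assert v.radius == pytest.approx(1.5e-3)
        assert v.length == pytest.approx(200e-3)
        assert v.v_mean == pytest.approx(0.13)
        assert np.allclose(v.axis_direction, (0, 0, 1))
        assert sc.domain_size[2] == pytest.approx(200e-3)

    def test_secondary_artery_parameters(self):
        sc = ft.make_scenario("secondary_artery")
        (v,) = sc.vessels
        assert (v.radius, v.length, v.v_mean) == pytest.approx(
            (0.3e-3, 40e-3, 0.08))

    def test_multi_pair_geometry(self, s6_scenario):
        sc = s6_scenario
        assert len(sc.vessels) == 18  # 9 pairs
        assert sc.domain_size == pytest.approx((21e-3, 21e-3, 26e-3))
        radii = sorted(v.radius for v in sc.vessels)
        assert radii[:12] == pytest.approx([0.4e-3] * 12)
        assert radii[12:] == pytest.approx([0.5e-3] * 6)
        # each pair is antiparallel: equal +z and -z flow counts
        signs = [v.flow_sign for v in sc.vessels]
        assert signs.count(1) == signs.count(-1) == 9
        # artery-vein axis separation = wall gap + 2R
        for (x, y, r_mm, gap_mm), (a, b) in zip(
                MULTI_PAIR_LAYOUT,
                [sc.vessels[i:i + 2] for i in range(0, 18, 2)]):
            sep = abs(a.axis_origin[1] - b.axis_origin[1])
            assert sep == pytest.approx(gap_mm * 1e-3 + 2 * r_mm * 1e-3)

    def test_counterflow_pair_focus_clearance(self):
        sc = ft.make_scenario("counterflow_pair")
        a, b = sc.vessels
        assert a.flow_sign == -b.flow_sign
        centre_x = sc.domain_size[0] / 2
        # inner walls 1 mm from the block centre on each side
        for v in (a, b):
            assert abs(v.axis_origin[0] - centre_x) == pytest.approx(
                v.radius + 1e-3)

    def test_unknown_name_and_bad_override(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ft.make_scenario("aorta")
        with pytest.raises(ValueError, match="lateral face"):
            ft.make_scenario("large_artery", transverse=2e-3)
        with pytest.raises(TypeError, match="unknown scenario options"):
            ft.make_scenario("large_artery", colour="red")

    def test_builders_are_pure(self):
        a = ft.make_scenario("multi_pair")
        b = ft.make_scenario("multi_pair")
        assert a == b


class TestRasterize:
    def test_parabolic_profile_extremes(self):
        sc = ft.make_scenario("large_artery", length=20e-3)
        grid = ft.Grid.for_box(sc.domain_size, 0.25e-3)
        f = ft.rasterize(sc, grid)
        (v,) = sc.vessels
        # centreline cell: w = 2 Vm (cell centres at 0.125 mm offsets from
        # the axis, so allow the tiny off-axis correction)
        assert f.w.max() == pytest.approx(2 * v.v_mean, rel=0.02)
        assert f.w.min() == 0.0
        assert np.all(f.w <= 2 * v.v_mean + 1e-12)
        assert np.all(f.w[f.tissue_mask] == 0.0)

    def test_lumen_cross_section_count(self):
        # ~pi (R/dx)^2 cells per slice, checked against the exact area
        sc = ft.make_scenario("large_artery", length=20e-3)
        grid = ft.Grid.for_box(sc.domain_size, 0.25e-3)
        f = ft.rasterize(sc, grid)
        per_slice = f.lumen_mask.sum() / grid.shape[2]
        exact = np.pi * (1.5 / 0.25) ** 2
        assert per_slice == pytest.approx(exact, rel=0.10)

    @pytest.mark.parametrize("spacing", [0.5e-3, 0.25e-3, 0.125e-3])
    def test_lumen_volume_converges(self, spacing):
        sc = ft.make_scenario("large_artery", length=20e-3, transverse=12e-3)
        grid = ft.Grid.for_box(sc.domain_size, spacing)
        f = ft.rasterize(sc, grid)
        vol = f.lumen_mask.sum() * np.prod(grid.spacing)
        exact = np.pi * (1.5e-3) ** 2 * 20e-3
        # first-order staircase convergence: error scales with spacing/R
        assert vol == pytest.approx(exact, rel=1.5 * spacing / 1.5e-3)

    def test_mean_velocity_is_v_mean(self):
        sc = ft.make_scenario("large_artery", length=10e-3, transverse=12e-3)
        grid = ft.Grid.for_box(sc.domain_size, 0.125e-3)
        f = ft.rasterize(sc, grid)
        k = grid.shape[2] // 2
        lum = f.lumen_mask[:, :, k]
        assert f.w[:, :, k][lum].mean() == pytest.approx(0.13, rel=0.03)

    def test_unresolved_vessel_errors_and_warns(self):
        sc = ft.make_scenario("secondary_artery", length=10e-3,
                              transverse=10e-3)
        with pytest.raises(ValueError, match="unresolved"):
            ft.rasterize(sc, ft.Grid.for_box(sc.domain_size, 0.5e-3))
        with pytest.warns(UserWarning, match="fewer than 2 cells"):
            ft.rasterize(sc, ft.Grid.for_box(sc.domain_size, 0.2e-3))

    def test_overlapping_vessels_rejected(self):
        v1 = ft.VesselSpec(radius=1e-3, length=10e-3, v_mean=0.1,
                           axis_origin=(5e-3, 5e-3, 0))
        v2 = ft.VesselSpec(radius=1e-3, length=10e-3, v_mean=0.1,
                           axis_origin=(5.5e-3, 5e-3, 0))
        sc = ft.Scenario(domain_size=(10e-3, 10e-3, 10e-3),
                         vessels=(v1, v2))
        with pytest.raises(ValueError, match="overlaps"):
            ft.rasterize(sc, ft.Grid.for_box(sc.domain_size, 0.25e-3))

    def test_inlets_at_upstream_faces(self, s6_fields):
        f = s6_fields
        nz = f.grid.shape[2]
        ks = np.unravel_index(f.inlet_cells, f.grid.shape)[2]
        assert set(np.unique(ks)) == {0, nz - 1}
        # arteries (+z flow) enter at k=0, veins at k=nz-1
        vz = f.velocity[2].reshape(-1)[f.inlet_cells]
        flat_k = ks
        assert np.all(vz[flat_k == 0] > 0)
        assert np.all(vz[flat_k == nz - 1] < 0)

    def test_axisym_matches_3d_lumen_fraction(self):
        sc = ft.make_scenario("large_artery", length=20e-3, transverse=16e-3)
        g2 = ft.Grid.for_cylinder(8e-3, 20e-3, 0.25e-3)
        f2 = ft.rasterize(sc, g2)
        (v,) = sc.vessels
        r = g2.axis_coords(0)
        assert np.all(f2.lumen_mask[r < v.radius - 1e-9, :])
        assert not np.any(f2.lumen_mask[r > v.radius + 1e-9, :])
        assert f2.w.max() == pytest.approx(2 * v.v_mean, rel=0.02)
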