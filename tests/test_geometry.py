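import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mucheck.errors import GeometryError
from mucheck.geometry import (
    BeamGeometry,
    DensityGrid,
    VoxelMask,
    air_gap,
    beam_direction,
    bev_projected_area,
    distal_surface_wed,
    mask_volume,
    water_equivalent_depth,
)

from .conftest import box_mask, brute_force_wed, sphere_mask, water_box


class TestBeamDirection:
    def test_gantry_zero_is_anterior(self):
        np.testing.assert_allclose(beam_direction(0, 0), [0, -1, 0], atol=1e-12)

    def test_gantry_ninety(self):
        np.testing.assert_allclose(beam_direction(90, 0), [-1, 0, 0], atol=1e-12)

    def test_matches_rotation_composition(self):
        # oracle: compose the gantry and couch rotations with scipy
        g, c = 37.0, 20.0
        rot = Rotation.from_euler("y", -c, degrees=True) * Rotation.from_euler(
            "z", -g, degrees=True
        )
        expected = rot.apply([0.0, -1.0, 0.0])
        np.testing.assert_allclose(beam_direction(g, c), expected, atol=1e-12)

    @pytest.mark.parametrize("g,c", [(123.4, 45.6), (359.0, 270.0), (-30.0, 400.0)])
    def test_unit_norm_and_modulo(self, g, c):
        d = beam_direction(g, c)
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(d, beam_direction(g + 360, c - 360), atol=1e-12)


class TestMaskVolume:
    def test_cube_125(self):
        density = water_box(10.0, 8.0, 0.1)
        mask = box_mask(density, (1.5, 2.0, 1.5), (6.5, 7.0, 6.5))
        assert mask_volume(mask) == pytest.approx(125.0, rel=1e-9)

    def test_single_voxel(self):
        occ = np.zeros((3, 3, 3), dtype=bool)
        occ[1, 1, 1] = True
        assert mask_volume(VoxelMask((0, 0, 0), (0.2, 0.2, 0.2), occ)) == pytest.approx(0.008)

    def test_sphere_within_one_percent_of_analytic(self):
        density = water_box(10.0, 10.0, 0.1)
        mask = sphere_mask(density, (5.0, 5.0, 5.0), 3.0)
        analytic = 4.0 / 3.0 * np.pi * 27.0
        assert mask_volume(mask) == pytest.approx(analytic, rel=0.01)

    def test_empty_mask_raises(self):
        empty = VoxelMask((0, 0, 0), (0.1, 0.1, 0.1), np.zeros((4, 4, 4), bool))
        with pytest.raises(GeometryError):
            mask_volume(empty)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(7)
        a = rng.random((10, 10, 10)) < 0.3
        b = (rng.random((10, 10, 10)) < 0.3) & ~a
        mk = lambda occ: VoxelMask((0, 0, 0), (0.15, 0.15, 0.15), occ)
        assert mask_volume(mk(a)) + mask_volume(mk(b)) == mask_volume(mk(a | b))


class TestBevProjectedArea:
    def test_cube_face_along_axis(self):
        density = water_box(10.0, 8.0, 0.1)
        mask = box_mask(density, (1.5, 2.0, 1.5), (6.5, 7.0, 6.5))
        area = bev_projected_area(mask, (0, -1, 0), 0.1)
        assert area == pytest.approx(25.0, abs=0.25)  # within a pixel ring

    def test_cube_at_45_degrees(self):
        # 0.05 cm digitization: silhouette error is voxelization-limited
        density = water_box(12.0, 12.0, 0.05)
        mask = box_mask(density, (3.5, 3.5, 3.5), (8.5, 8.5, 8.5))
        d = np.array([-1.0, -1.0, 0.0]) / np.sqrt(2)
        # analytic shadow of a cube rotated in a face plane: A*(cos+sin)
        assert bev_projected_area(mask, d, 0.025) == pytest.approx(25.0 * np.sqrt(2), rel=0.01)

    def test_sphere_disc_along_axis(self):
        density = water_box(10.0, 10.0, 0.1)
        mask = sphere_mask(density, (5.0, 5.0, 5.0), 3.0)
        assert bev_projected_area(mask, (0, -1, 0), 0.1) == pytest.approx(np.pi * 9, rel=0.01)

    def test_sphere_disc_oblique(self):
        density = water_box(10.0, 10.0, 0.05)
        mask = sphere_mask(density, (5.0, 5.0, 5.0), 3.0)
        d = np.array([1.0, 2.0, -0.5]) / np.sqrt(5.25)
        assert bev_projected_area(mask, d, 0.025) == pytest.approx(np.pi * 9, rel=0.01)

    def test_translation_along_beam_axis_invariant(self):
        density = water_box(20.0, 8.0, 0.1)
        a1 = bev_projected_area(box_mask(density, (2, 3, 2), (5, 6, 5)), (0, -1, 0), 0.1)
        a2 = bev_projected_area(box_mask(density, (2, 12, 2), (5, 15, 5)), (0, -1, 0), 0.1)
        assert a1 == pytest.approx(a2, rel=0.005)

    def test_coarse_pixel_rejected(self):
        density = water_box(5.0, 5.0, 0.1)
        mask = box_mask(density, (1, 1, 1), (4, 4, 4))
        with pytest.raises(GeometryError):
            bev_projected_area(mask, (0, -1, 0), 0.25)


class TestWaterEquivalentDepth:
    def test_uniform_water_twenty_cm(self):
        density = water_box(30.0, 6.0, 0.1)
        # entry surface is the +y grid face at y=30
        wed = water_equivalent_depth((3.0, 10.0, 3.0), (0, -1, 0), density)
        assert wed == pytest.approx(20.0, abs=1e-9)

    def test_point_on_surface_is_zero(self):
        density = water_box(10.0, 6.0, 0.1)
        assert water_equivalent_depth((3.0, 10.0, 3.0), (0, -1, 0), density) == pytest.approx(0.0, abs=1e-9)

    def test_layered_phantom_brute_force(self):
        # 5 cm of rsp 0.5 on top of water; 10 cm geometric depth -> 7.5 cm WED
        density = water_box(20.0, 6.0, 0.1)
        rsp = density.rsp.copy()
        rsp[:, int(15.0 / 0.1) :, :] = 0.5
        density = DensityGrid(density.origin, density.spacing, rsp)
        p = (3.0, 10.0, 3.0)
        wed = water_equivalent_depth(p, (0, -1, 0), density)
        assert wed == pytest.approx(7.5, abs=1e-9)
        assert wed == pytest.approx(brute_force_wed(p, density), abs=0.01)

    def test_oblique_direction_uniform_water(self):
        density = water_box(30.0, 30.0, 0.1)
        d = np.array([0.0, -2.0, 1.0])
        d = d / np.linalg.norm(d)
        p = np.array([15.0, 15.0, 15.0])
        # in uniform water the WED equals the distance to the grid boundary
        # upstream: solve exit of the reverse ray analytically
        t_exit = min((30.0 - p[1]) / 2.0 * np.sqrt(5), 15.0 / 1.0 * np.sqrt(5))
        assert water_equivalent_depth(p, d, density) == pytest.approx(t_exit, rel=1e-9)

    def test_point_outside_grid_raises(self):
        density = water_box(10.0, 6.0, 0.1)
        with pytest.raises(GeometryError):
            water_equivalent_depth((3.0, 11.0, 3.0), (0, -1, 0), density)

    def test_randomized_layered_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            density = water_box(20.0, 4.0, 0.2)
            rsp = np.ones(density.shape)
            edges = np.sort(rng.integers(5, density.shape[1] - 5, size=3))
            vals = rng.uniform(0.0, 2.0, size=4)
            prev = 0
            for e, v in zip(edges, vals):
                rsp[:, prev:e, :] = v
                prev = e
            rsp[:, prev:, :] = vals[-1]
            density = DensityGrid(density.origin, density.spacing, rsp)
            p = (2.0, float(rng.uniform(1.0, 10.0)), 2.0)
            try:
                wed = water_equivalent_depth(p, (0, -1, 0), density)
            except GeometryError:
                continue  # point generated outside the "patient"
            assert wed == pytest.approx(brute_force_wed(p, density), abs=0.01)


class TestDistalSurfaceWed:
    def test_flat_distal_face(self):
        density = water_box(30.0, 8.0, 0.1)
        # cube occupying depths 15..20 below the y=30 entry face
        mask = box_mask(density, (1.5, 10.0, 1.5), (6.5, 15.0, 6.5))
        res = distal_surface_wed(mask, density, (0, -1, 0), 0.1)
        assert res.mean_cm == pytest.approx(20.0, abs=0.06)
        assert np.ptp(res.per_ray_cm) < 0.06

    def test_hemisphere_mean_depth(self):
        # sphere r=3 centered at depth 10: mean distal depth = 10 + 2r/3
        density = water_box(20.0, 10.0, 0.1)
        mask = sphere_mask(density, (5.0, 10.0, 5.0), 3.0)
        res = distal_surface_wed(mask, density, (0, -1, 0), 0.1)
        assert res.mean_cm == pytest.approx(12.0, rel=0.01)

    def test_lateral_translation_invariance(self):
        density = water_box(30.0, 12.0, 0.1)
        m1 = box_mask(density, (2.0, 10.0, 2.0), (6.0, 14.0, 6.0))
        m2 = box_mask(density, (6.0, 10.0, 6.0), (10.0, 14.0, 10.0))
        r1 = distal_surface_wed(m1, density, (0, -1, 0), 0.1)
        r2 = distal_surface_wed(m2, density, (0, -1, 0), 0.1)
        assert r1.mean_cm == pytest.approx(r2.mean_cm, abs=1e-9)

    def test_monotone_when_translated_deeper(self):
        density = water_box(30.0, 8.0, 0.1)
        means = []
        for depth in (8.0, 12.0, 16.0, 20.0):
            mask = box_mask(density, (2.0, 30.0 - depth, 2.0), (6.0, 30.0 - depth + 4.0, 6.0))
            means.append(distal_surface_wed(mask, density, (0, -1, 0), 0.1).mean_cm)
        diffs = np.diff(means)
        assert np.all(diffs > 0)
        np.testing.assert_allclose(diffs, 4.0, atol=0.1)

    def test_no_intersection_raises(self):
        density = water_box(10.0, 6.0, 0.1)
        mask = box_mask(density, (1, 1, 1), (3, 3, 3))
        with pytest.raises(GeometryError):
            distal_surface_wed(mask, density, (0, -1, 0), 0.25)


class TestAirGap:
    def _beam(self, density, depth, face_distance):
        iso = np.array([density.upper[0] / 2, density.upper[1] - depth, density.upper[2] / 2])
        return BeamGeometry(0.0, 0.0, iso, range_shifted=True, shifter_face_distance=face_distance)

    def test_reference_one_cm_gap_exact(self):
        density = water_box(20.0, 8.0, 0.1)
        beam = self._beam(density, 5.0, 6.0)  # face 6 upstream of iso, surface 5
        assert air_gap(density, beam) == pytest.approx(1.0, abs=1e-9)

    def test_face_touching_surface(self):
        density = water_box(20.0, 8.0, 0.1)
        beam = self._beam(density, 5.0, 5.0)
        assert air_gap(density, beam) == pytest.approx(0.0, abs=1e-9)

    def test_oblique_surface_matches_ray_plane_solution(self):
        # surface plane tilted 30 degrees to the beam axis
        spacing = 0.05
        density = water_box(10.0, 6.0, spacing)
        idx = np.indices(density.shape, dtype=float)
        x = (idx[0] + 0.5) * spacing
        y = (idx[1] + 0.5) * spacing
        slope = np.tan(np.deg2rad(30.0))
        rsp = np.where(y < 6.0 + slope * (x - 3.0), 1.0, 0.0)
        density = DensityGrid(density.origin, density.spacing, rsp)
        iso = np.array([3.0, 2.0, 3.0])
        beam = BeamGeometry(0.0, 0.0, iso, range_shifted=True, shifter_face_distance=8.0)
        # analytic: face at y=10, surface at y = 6 + slope*0 = 6 on the axis
        assert air_gap(density, beam) == pytest.approx(4.0, abs=1.5 * spacing)

    def test_axis_misses_grid_raises(self):
        density = water_box(10.0, 6.0, 0.1)
        beam = BeamGeometry(0.0, 0.0, (30.0, 5.0, 3.0), range_shifted=True, shifter_face_distance=10.0)
        with pytest.raises(GeometryError):
            air_gap(density, beam)

    def test_face_inside_patient_raises(self):
        density = water_box(20.0, 8.0, 0.1)
        beam = self._beam(density, 5.0, -1.0)  # face 1 cm downstream of iso, inside water
        with pytest.raises(GeometryError):
            air_gap(density, beam)

    def test_open_beam_rejected(self):
        density = water_box(10.0, 6.0, 0.1)
        beam = BeamGeometry(0.0, 0.0, (3.0, 5.0, 3.0), range_shifted=False)
        with pytest.raises(GeometryError):
            air_gap(density, beam)
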