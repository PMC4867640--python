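"""Rotation, footprint projection, FOV calibration and image selection."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from auvspat.geometry import (
    CameraModel,
    PoseRecord,
    calibrate_fov,
    locate_observation,
    project_footprint,
    project_footprints,
    rotation_matrices,
    rotation_matrix,
    select_images,
    shoelace_area,
)


def level_pose(altitude=3.2, heading=0.0, pitch=0.0, roll=0.0, e=0.0, n=0.0):
    return PoseRecord(0.0, e, n, 4850.0, altitude, pitch, roll, heading)


class TestRotationMatrix:
    def test_zero_attitude_is_identity_in_ne_plane(self):
        r = rotation_matrix(0.0, 0.0, 0.0)
        # forward -> north, starboard -> east, down -> -up
        np.testing.assert_allclose(r @ [1, 0, 0], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(r @ [0, 1, 0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(r @ [0, 0, 1], [0, 0, -1], atol=1e-12)

    def test_heading_90_maps_forward_to_east(self):
        r = rotation_matrix(90.0, 0.0, 0.0)
        np.testing.assert_allclose(r @ [1, 0, 0], [1, 0, 0], atol=1e-12)

    def test_orthonormal_proper_for_random_attitudes(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0, 360, 1000)
        p = rng.uniform(-89, 89, 1000)
        ro = rng.uniform(-89, 89, 1000)
        mats = rotation_matrices(h, p, ro)
        eye = np.einsum("nij,nik->njk", mats, mats)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape), atol=1e-12)
        np.testing.assert_allclose(np.linalg.det(mats), 1.0, atol=1e-12)

    def test_matches_scipy_euler_convention(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            h, p, r = rng.uniform(0, 360), rng.uniform(-80, 80), rng.uniform(-80, 80)
            ours = rotation_matrix(h, p, r)
            # intrinsic Z-Y-X in the NED frame, then NED -> ENU axes
            ned = ScipyRotation.from_euler("ZYX", [h, p, r], degrees=True).as_matrix()
            perm = np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, -1]])
            np.testing.assert_allclose(ours, perm @ ned, atol=1e-12)


class TestFootprintProjection:
    def test_vertical_area_at_target_altitude(self, cameras):
        fp = project_footprint(level_pose(), cameras["vertical"])
        assert fp.area == pytest.approx(2.4, rel=1e-6)

    def test_oblique_area_at_target_altitude(self, cameras):
        fp = project_footprint(level_pose(), cameras["oblique"])
        assert fp.area == pytest.approx(16.5, rel=1e-6)

    def test_vertical_area_scales_with_altitude_squared(self, cameras):
        a1 = project_footprint(level_pose(3.2), cameras["vertical"]).area
        a2 = project_footprint(level_pose(6.4), cameras["vertical"]).area
        assert a2 == pytest.approx(4.0 * a1, rel=1e-9)

    def test_area_invariant_under_heading(self, cameras):
        areas = [
            project_footprint(level_pose(heading=h), cameras["oblique"]).area
            for h in (0.0, 37.0, 123.4, 270.0)
        ]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-9)

    def test_small_attitude_changes_area_smoothly(self, cameras):
        # exact trapezoid area grows ~(tan(t+h)-tan(t-h))/(2 tan h) per
        # tilted axis: +2.5% at 5 deg roll for the 14.8 deg across
        # half-FOV, so 3% is the tight smoothness bound here
        base = project_footprint(level_pose(), cameras["vertical"]).area
        for p, r in [(5, 0), (-5, 0), (0, 5), (0, -5)]:
            a = project_footprint(level_pose(pitch=p, roll=r), cameras["vertical"]).area
            assert abs(a - base) / base < 0.03

    def test_area_equals_shoelace_of_corners(self, cameras):
        fp = project_footprint(level_pose(pitch=3, roll=-2, heading=45), cameras["oblique"])
        assert fp.area == pytest.approx(float(shoelace_area(fp.corners)), rel=1e-12)

    def test_extreme_pitch_invalidates_oblique_footprint(self, cameras):
        # nose-up pitch lifts the far rays above the horizon
        with pytest.raises(ValueError, match="invalid"):
            project_footprint(level_pose(pitch=40.0), cameras["oblique"])
        batch = project_footprints(
            np.zeros(1), np.zeros(1), np.full(1, 3.2), np.zeros(1), np.full(1, 40.0),
            np.zeros(1), cameras["oblique"],
        )
        assert not batch.valid[0]
        assert batch.area[0] == 0.0

    def test_oblique_footprint_lies_ahead_of_vehicle(self, cameras):
        fp = project_footprint(level_pose(heading=0.0), cameras["oblique"])
        assert np.all(fp.corners[:, 1] > 0)  # all corners north of the AUV


class TestCalibrateFov:
    def test_vertical_reprojects_target_area_within_1pct(self):
        cam = calibrate_fov("vertical", 2.4, 3.2)
        assert project_footprint(level_pose(), cam).area == pytest.approx(2.4, rel=0.01)

    def test_oblique_reprojects_target_area_within_1pct(self):
        cam = calibrate_fov("oblique", 16.5, 3.2)
        assert project_footprint(level_pose(), cam).area == pytest.approx(16.5, rel=0.01)

    def test_vertical_tangents_scale_sqrt2_for_doubled_area(self):
        c1 = calibrate_fov("vertical", 2.4, 3.2)
        c2 = calibrate_fov("vertical", 4.8, 3.2)
        t1 = math.tan(math.radians(c1.half_fov_along))
        t2 = math.tan(math.radians(c2.half_fov_along))
        assert t2 / t1 == pytest.approx(math.sqrt(2.0), rel=1e-9)

    def test_aspect_ratio_fixed_by_sensor(self):
        cam = calibrate_fov("vertical", 2.4, 3.2)
        ratio = math.tan(math.radians(cam.half_fov_across)) / math.tan(
            math.radians(cam.half_fov_along)
        )
        assert ratio == pytest.approx(2448 / 2048, rel=1e-9)

    def test_unachievable_oblique_area_raises(self):
        with pytest.raises(ValueError, match="no oblique FOV"):
            calibrate_fov("oblique", 1e9, 3.2, mount_angle=5.0)


class TestLocateObservation:
    def test_centre_pixel_level_vertical_is_beneath_vehicle(self, cameras):
        e, n = locate_observation(
            level_pose(e=100.0, n=200.0), cameras["vertical"], (1023.5, 1223.5)
        )
        assert (e, n) == pytest.approx((100.0, 200.0), abs=1e-9)

    def test_corner_pixels_map_to_footprint_corners(self, cameras):
        pose = level_pose(heading=30.0, pitch=2.0, roll=-1.0)
        fp = project_footprint(pose, cameras["oblique"])
        rows, cols = cameras["oblique"].pixel_dims
        pix = [(0, 0), (0, cols - 1), (rows - 1, cols - 1), (rows - 1, 0)]
        located = np.array([locate_observation(pose, cameras["oblique"], p) for p in pix])
        # corner ring order is (--, -+, ++, +-) over (along, across)
        np.testing.assert_allclose(np.sort(located, axis=0), np.sort(fp.corners, axis=0), atol=1e-9)

    def test_located_pixels_fall_inside_footprint(self, cameras):
        pose = level_pose(heading=77.0, pitch=4.0, roll=3.0)
        fp = project_footprint(pose, cameras["oblique"])
        poly = fp.polygon().buffer(1e-9)
        rng = np.random.default_rng(3)
        import shapely

        for _ in range(200):
            pix = (rng.uniform(0, 2047), rng.uniform(0, 2447))
            pt = shapely.Point(locate_observation(pose, cameras["oblique"], pix))
            assert poly.contains(pt)


class TestSelectImages:
    def make_set(self, cam, altitudes):
        n = len(altitudes)
        return project_footprints(
            np.arange(n, dtype=float),
            np.zeros(n),
            np.asarray(altitudes, dtype=float),
            np.zeros(n),
            np.zeros(n),
            np.zeros(n),
            cam,
            timestamp=np.arange(n, dtype=float),
        )

    def test_altitude_window_vertical(self, cameras):
        fps = self.make_set(cameras["vertical"], [1.8, 2.0, 4.0, 4.2])
        kept = select_images(fps)
        assert len(kept) == 2
        np.testing.assert_allclose(kept.altitude, [2.0, 4.0])

    def test_oblique_stride_two(self, cameras):
        fps = self.make_set(cameras["oblique"], [3.2, 3.2, 3.2, 3.2])
        assert len(select_images(fps)) == 2

    def test_vertical_never_decimated(self, cameras):
        fps = self.make_set(cameras["vertical"], [3.2] * 7)
        assert len(select_images(fps)) == 7

    def test_effort_is_sum_of_retained_areas(self, cameras):
        fps = self.make_set(cameras["vertical"], [3.2, 3.2, 9.0])
        kept = select_images(fps)
        assert kept.effort_area_km2() == pytest.approx(2 * 2.4 / 1e6, rel=1e-6)
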