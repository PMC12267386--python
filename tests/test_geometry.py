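"""Calibration, grid construction, base-sphere and cube-volume geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachtime.geometry import (
    CubeStimulus,
    GeometryError,
    MotionSpec,
    Vec3,
    build_grid,
    calibrate,
    cube_contains,
    cube_position_at,
    in_base,
)



def angle_deg(u: Vec3, v: Vec3) -> float:
    c = u.unit().dot(v.unit())
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


class TestCalibrate:
    @pytest.mark.parametrize(
        "b, r, d",
        [
            (Vec3(0, 1.2, 0), Vec3(0, 1.2, 0.5), 0.5),
            (Vec3(0, 1.0, 0), Vec3(0.3, 1.0, 0.4), 0.5),  # 3-4-5 triangle
        ],
    )
    def test_distance_is_euclidean(self, b, r, d):
        assert calibrate(b, r).distance_d == pytest.approx(d, abs=1e-12)

    def test_coincident_anchors_rejected(self):
        with pytest.raises(GeometryError):
            calibrate(Vec3(0, 1, 0), Vec3(0, 1, 0))

    def test_nonfinite_components_rejected(self):
        with pytest.raises(GeometryError):
            Vec3(float("nan"), 0, 0)


def oracle_grid(cal, elevation_deg=30.0, azimuth_deg=35.0):
    """Rotation-matrix construction: elevation about the lateral (x) axis,
    then azimuth about the vertical (y) axis, applied to the forward unit."""

    def rot_x(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def rot_y(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    fwd = np.array([0.0, 0.0, 1.0])
    rows = (1.0, 0.0, -1.0)
    cols = (-1.0, 0.0, 1.0)
    out = []
    for i in range(9):
        e = math.radians(rows[i // 3] * elevation_deg)
        a = math.radians(cols[i % 3] * azimuth_deg)
        # positive elevation tips the forward vector upward: rotate by -e
        # about +x in this frame; positive azimuth swings it to the right
        d = rot_y(a) @ rot_x(-e) @ fwd
        out.append(np.array(cal.location_b.as_tuple()) + cal.distance_d * d)
    return out


class TestGrid:
    def test_all_locations_at_distance_d(self, cal, grid):
        for i in range(1, 10):
            r = (grid.location(i) - cal.location_b).norm()
            assert r == pytest.approx(cal.distance_d, abs=1e-9)

    def test_center_aligned_with_b(self, cal, grid):
        v = grid.location(5) - cal.location_b
        assert v.x == pytest.approx(0.0, abs=1e-12)
        assert v.y == pytest.approx(0.0, abs=1e-12)

    def test_vertical_offset_30_degrees(self, cal, grid):
        b = cal.location_b
        assert angle_deg(grid.location(5) - b, grid.location(2) - b) == pytest.approx(
            30.0, abs=1e-9
        )

    def test_horizontal_offset_35_degrees(self, cal, grid):
        b = cal.location_b
        assert angle_deg(grid.location(5) - b, grid.location(6) - b) == pytest.approx(
            35.0, abs=1e-9
        )

    def test_location_2_coordinates(self, grid):
        # b=(0,1.2,0), d=0.5 straight ahead: directly-above location raises
        # y by d*sin30 and shortens forward reach to d*cos30
        loc2 = grid.location(2)
        assert loc2.x == pytest.approx(0.0, abs=1e-12)
        assert loc2.y == pytest.approx(1.2 + 0.5 * math.sin(math.radians(30)), abs=1e-9)
        assert loc2.z == pytest.approx(0.5 * math.cos(math.radians(30)), abs=1e-9)

    def test_matches_rotation_matrix_oracle_noncorner_exact(self, cal, grid):
        oracle = oracle_grid(cal)
        for i in (2, 4, 5, 6, 8):  # non-corner: single-axis rotations
            got = np.array(grid.location(i).as_tuple())
            assert np.allclose(got, oracle[i - 1], atol=1e-12)

    def test_corner_parameterization(self, cal, grid):
        # corners combine angles as dir(e,a) = (cos e sin a, sin e, cos e cos a)
        b, d = cal.location_b, cal.distance_d
        e, a = math.radians(30), math.radians(-35)
        expect = Vec3(
            d * math.cos(e) * math.sin(a), d * math.sin(e), d * math.cos(e) * math.cos(a)
        )
        got = grid.location(1) - b
        assert got.as_tuple() == pytest.approx(expect.as_tuple(), abs=1e-12)

    def test_mirror_symmetry(self, cal, grid):
        b = cal.location_b
        # azimuth reflection maps column 1 onto column 3
        for left, right in ((1, 3), (4, 6), (7, 9)):
            vl, vr = grid.location(left) - b, grid.location(right) - b
            assert vl.x == pytest.approx(-vr.x, abs=1e-12)
            assert vl.y == pytest.approx(vr.y, abs=1e-12)
            assert vl.z == pytest.approx(vr.z, abs=1e-12)
        # elevation reflection maps row 1 onto row 3
        for top, bottom in ((1, 7), (2, 8), (3, 9)):
            vt, vb = grid.location(top) - b, grid.location(bottom) - b
            assert vt.y == pytest.approx(-vb.y, abs=1e-12)
            assert vt.x == pytest.approx(vb.x, abs=1e-12)
            assert vt.z == pytest.approx(vb.z, abs=1e-12)

    def test_arbitrary_forward_keeps_distances(self, cal):
        g = build_grid(cal, forward=Vec3(1.0, 0.3, 1.0))  # vertical part ignored
        for i in range(1, 10):
            assert (g.location(i) - cal.location_b).norm() == pytest.approx(
                cal.distance_d, abs=1e-9
            )

    def test_zero_forward_rejected(self, cal):
        with pytest.raises(GeometryError):
            build_grid(cal, forward=Vec3(0.0, 1.0, 0.0))


class TestInBase:
    def test_center_inside(self, cal):
        assert in_base(cal.location_b, cal)

    def test_boundary_inclusive(self, cal):
        p = cal.location_b + Vec3(0.028, 0, 0)
        assert in_base(p, cal)

    def test_just_outside(self, cal):
        p = cal.location_b + Vec3(0.0281, 0, 0)
        assert not in_base(p, cal)


class TestCubeContains:
    def setup_method(self):
        self.cube = CubeStimulus(face_center=Vec3(0.0, 1.2, 0.5))
        self.inward = Vec3(0.0, 0.0, 1.0)

    def test_face_center_inside(self):
        assert cube_contains(self.cube.face_center, self.cube, self.inward)

    def test_lateral_overshoot_outside(self):
        p = self.cube.face_center + Vec3(0.06, 0, 0)
        assert not cube_contains(p, self.cube, self.inward)

    def test_depth_inside(self):
        p = self.cube.face_center + Vec3(0, 0, 0.05)
        assert cube_contains(p, self.cube, self.inward)

    def test_in_front_of_face_outside(self):
        p = self.cube.face_center + Vec3(0, 0, -0.01)
        assert not cube_contains(p, self.cube, self.inward)

    def test_behind_cube_outside(self):
        p = self.cube.face_center + Vec3(0, 0, 0.11)
        assert not cube_contains(p, self.cube, self.inward)

    def test_zero_inward_rejected(self):
        with pytest.raises(GeometryError):
            cube_contains(self.cube.face_center, self.cube, Vec3(0, 0, 0))


class TestCubeMotion:
    def test_onset_at_origin(self, grid):
        m = MotionSpec(origin_index=1, target_index=9, speed=0.6)
        assert cube_position_at(grid, m, 0.0).as_tuple() == pytest.approx(
            grid.location(1).as_tuple()
        )

    def test_constant_velocity_midpoint(self, cal):
        g = build_grid(cal)
        m = MotionSpec(origin_index=4, target_index=6, speed=0.6)
        gap = (g.location(6) - g.location(4)).norm()
        t_mid = gap / 2 / 0.6
        p = cube_position_at(g, m, t_mid)
        mid = g.location(4) + (g.location(6) - g.location(4)).scale(0.5)
        assert p.as_tuple() == pytest.approx(mid.as_tuple(), abs=1e-12)

    def test_continues_past_target(self, grid):
        m = MotionSpec(origin_index=4, target_index=6, speed=0.9)
        far = cube_position_at(grid, m, 10.0)
        assert (far - grid.location(4)).norm() == pytest.approx(9.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        t1=st.floats(0, 2, allow_nan=False),
        dt=st.floats(0.001, 2, allow_nan=False),
        speed=st.floats(0.1, 2, allow_nan=False),
    )
    def test_displacement_norm_is_speed_times_dt(self, t1, dt, speed):
        cal = calibrate(Vec3(0, 1.2, 0), Vec3(0, 1.2, 0.5))
        g = build_grid(cal)
        m = MotionSpec(origin_index=2, target_index=7, speed=speed)
        d = cube_position_at(g, m, t1 + dt) - cube_position_at(g, m, t1)
        assert d.norm() == pytest.approx(speed * dt, abs=1e-9)

    def test_negative_time_rejected(self, grid):
        with pytest.raises(GeometryError):
            cube_position_at(grid, MotionSpec(1, 2, 0.6), -0.1)

    def test_degenerate_motion_rejected(self):
        with pytest.raises(GeometryError):
            MotionSpec(origin_index=3, target_index=3, speed=0.6)
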