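"""Euler rotation, azimuth recovery and world/local transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tribs import build_rotation, rest_local_p4, solve_alpha, world_to_local
from tribs.errors import FrameTagError, InconsistentMarkerError
from tribs.frames import EulerTransform, build_transform
from tribs.model import Point3

angles = st.floats(-180.0, 180.0, allow_nan=False)


class TestBuildRotation:
    def test_zero_rotation_is_identity(self):
        assert np.allclose(build_rotation(0, 0, 0), np.eye(3), atol=1e-15)

    def test_pure_z_rotation(self):
        expected = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(build_rotation(90, 0, 0), expected, atol=1e-15)

    def test_composition_order_z_y_x(self):
        a, b, g = 31.0, -47.0, 112.0
        rz, ry, rx = build_rotation(a, 0, 0), build_rotation(0, b, 0), build_rotation(0, 0, g)
        assert np.allclose(build_rotation(a, b, g), rz @ ry @ rx, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(angles, angles, angles)
    def test_orthonormal_unit_determinant(self, a, b, g):
        r = build_rotation(a, b, g)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert abs(np.linalg.det(r) - 1.0) < 1e-12


class TestRestLocalP4:
    def test_unit_clavicle_coordinates(self, model):
        from tribs import default_model

        p4 = rest_local_p4(default_model((1.0, 1.0, 1.0, 1.0)))
        assert p4.frame_tag == "local"
        assert p4.xyz == pytest.approx([-0.3420201433, 0.0, 0.9396926208], abs=1e-9)

    def test_norm_equals_clavicle_length(self, model):
        assert np.linalg.norm(rest_local_p4(model).xyz) == pytest.approx(model.L1)


class TestSolveAlpha:
    def _forward(self, model, alpha, beta, gamma, p3):
        r = build_rotation(alpha, beta, gamma)
        return Point3.from_array(r @ rest_local_p4(model).xyz + p3, "world")

    def test_identity_transform(self, model):
        p3 = Point3(0, 0, 0, "world")
        p4 = Point3.from_array(rest_local_p4(model).xyz, "world")
        assert solve_alpha(p3, p4, 0.0, 0.0, model) == pytest.approx(0.0, abs=1e-9)

    def test_single_round_trip(self, model):
        p3 = np.array([12.0, -400.0, 950.0])
        p4 = self._forward(model, 30.0, 0.0, 90.0, p3)
        got = solve_alpha(Point3.from_array(p3, "world"), p4, 0.0, 90.0, model)
        assert got == pytest.approx(30.0, abs=1e-6)

    def test_grid_round_trip(self, model):
        p3 = np.array([55.0, -20.0, 1300.0])
        for alpha in range(-170, 171, 10):
            p4 = self._forward(model, alpha, 0.0, 90.0, p3)
            got = solve_alpha(Point3.from_array(p3, "world"), p4, 0.0, 90.0, model)
            assert got == pytest.approx(alpha, abs=1e-6)

    def test_scale_invariance(self, model):
        from tribs import default_model

        p3 = np.array([55.0, -20.0, 1300.0])
        p4 = self._forward(model, 73.0, 10.0, 80.0, p3)
        big = default_model(model.lengths * 3.0)
        got = solve_alpha(
            Point3.from_array(p3 * 3.0, "world"),
            Point3.from_array(p4.xyz * 3.0, "world"),
            10.0,
            80.0,
            big,
        )
        assert got == pytest.approx(73.0, abs=1e-6)

    def test_length_mismatch_rejected(self, model):
        p3 = Point3(0, 0, 0, "world")
        p4 = Point3(0, 0, model.L1 * 1.2, "world")
        with pytest.raises(InconsistentMarkerError):
            solve_alpha(p3, p4, 0.0, 90.0, model)

    def test_gimbal_lock_warning(self):
        with pytest.warns(UserWarning, match="gimbal"):
            EulerTransform(0.0, 90.0, 0.0, np.zeros(3))


class TestWorldToLocal:
    def test_origin_maps_p3_to_zero(self, model):
        p3 = np.array([10.0, 20.0, 30.0])
        t = EulerTransform(25.0, 0.0, 90.0, p3)
        out = world_to_local(Point3.from_array(p3, "world"), t)
        assert out.frame_tag == "local"
        assert np.allclose(out.xyz, 0.0, atol=1e-12)

    def test_identity_when_no_transform(self):
        t = EulerTransform(0.0, 0.0, 0.0, np.zeros(3))
        p = Point3(3.0, -4.0, 5.0, "world")
        assert np.allclose(world_to_local(p, t).xyz, p.xyz)

    def test_round_trip_identity(self, rng):
        t = EulerTransform(33.0, 12.0, -70.0, np.array([5.0, 6.0, 7.0]))
        pts = rng.normal(size=(50, 3)) * 300.0
        back = t.to_world(t.to_local(pts))
        assert np.allclose(back, pts, atol=1e-10)

    def test_frame_tag_enforced(self):
        t = EulerTransform(0.0, 0.0, 0.0, np.zeros(3))
        with pytest.raises(FrameTagError):
            world_to_local(Point3(1, 2, 3, "local"), t)


def test_build_transform_consistent_with_solve(model):
    p3 = np.array([120.0, 40.0, 900.0])
    r = build_rotation(-140.0, 0.0, 90.0)
    p4 = r @ rest_local_p4(model).xyz + p3
    t = build_transform(
        Point3.from_array(p3, "world"), Point3.from_array(p4, "world"), 0.0, 90.0, model
    )
    assert t.alpha_deg == pytest.approx(-140.0, abs=1e-6)
    # the transform sends the measured P4 back onto the rest-pose local P4
    assert np.allclose(t.to_local(p4), rest_local_p4(model).xyz, atol=1e-9)
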