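"""Euclidean-route angle formulas, degeneracies and invariances."""

import math

import numpy as np
import pytest

from tribs import (
    build_point_set,
    clavicle_angles,
    default_model,
    elbow_angle,
    extract_pose,
    humeral_category,
    humerus_angles_psi,
    humerus_angles_vector,
    wrist_angles,
)
from tribs.errors import GeometryError, MissingMarkerError
from tribs.euclidean_angles import HumerusProjection
from tribs.frames import EulerTransform, build_transform, rest_local_p4
from tribs.model import ANGLE_LABELS, Point3
from tribs.synthetic import forward_pose
from tribs.virtual_points import PointSet, clavicle_refs, humerus_refs

from conftest import marker_dict


def clavicle_pointset(model, p4):
    p1, p2 = clavicle_refs(model)
    return PointSet({1: p1, 2: p2, 4: np.asarray(p4, dtype=float)})


def humerus_pointset(model, p8, p9):
    p5, p6, p7 = humerus_refs(np.asarray(p8, dtype=float), model)
    return PointSet({5: p5, 6: p6, 7: p7, 8: np.asarray(p8, float), 9: np.asarray(p9, float)})


class TestClavicleAngles:
    def test_rest_pose_is_zero(self, model):
        pts = clavicle_pointset(model, rest_local_p4(model).xyz)
        assert clavicle_angles(pts) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_elevation_thirty_degrees(self, model):
        # y4 = L1/2 with the horizontal remainder along the rest direction
        phi = math.radians(model.clavicle_offset_deg)
        horiz = math.sqrt(model.L1**2 - (model.L1 / 2) ** 2)
        p4 = np.array([-math.sin(phi) * horiz, model.L1 / 2, math.cos(phi) * horiz])
        t1, t2 = clavicle_angles(clavicle_pointset(model, p4))
        assert t1 == pytest.approx(30.0, abs=1e-9)
        assert t2 == pytest.approx(0.0, abs=1e-9)

    def test_protraction_thirty_degrees(self, model):
        phi = math.radians(model.clavicle_offset_deg)
        e1 = np.array([math.cos(phi), 0.0, math.sin(phi)])
        e2 = np.array([-math.sin(phi), 0.0, math.cos(phi)])
        p4 = model.L1 * (0.5 * e1 + math.sqrt(0.75) * e2)
        t1, t2 = clavicle_angles(clavicle_pointset(model, p4))
        assert t2 == pytest.approx(30.0, abs=1e-9)
        assert t1 == pytest.approx(0.0, abs=1e-9)

    def test_gross_argument_excess_is_error(self, model):
        pts = clavicle_pointset(model, [0.0, model.L1 * 1.01, 0.0])
        with pytest.raises(GeometryError):
            clavicle_angles(pts)


class TestHumerusAngles:
    def test_diagonal_pose_hand_values(self, model):
        p9 = np.array([1.0, -1.0, 0.0]) * model.L2 / math.sqrt(2)
        t3, t4, t5 = humerus_angles_vector(humerus_pointset(model, np.zeros(3), p9))
        assert (t3, t4, t5) == pytest.approx((0.0, 45.0, 90.0), abs=1e-9)

    def test_vertical_humerus_theta3_undefined(self, model):
        p9 = np.array([0.0, -model.L2, 0.0])
        t3, t4, t5 = humerus_angles_vector(humerus_pointset(model, np.zeros(3), p9))
        assert math.isnan(t3)
        assert (t4, t5) == pytest.approx((0.0, 90.0), abs=1e-9)

    def test_psi_hand_values(self):
        assert humerus_angles_psi(HumerusProjection(-1.0, 1.0, 0.0)) == pytest.approx(
            (0.0, 45.0, 90.0), abs=1e-9
        )
        t3, t4, t5 = humerus_angles_psi(HumerusProjection(0.0, 1.0, 0.0))
        assert math.isnan(t3)
        assert (t4, t5) == pytest.approx((0.0, 90.0), abs=1e-9)

    def test_degenerate_humerus_rejected(self, model):
        with pytest.raises(GeometryError):
            humerus_angles_psi(HumerusProjection(0.0, 0.0, 0.0))
        with pytest.raises(GeometryError):
            humerus_angles_vector(humerus_pointset(model, np.zeros(3), np.zeros(3)))

    def test_vector_equals_psi_on_random_poses(self, model, rng):
        """The cross-product and coordinate-difference routes are identical."""
        for _ in range(1000):
            psi = rng.normal(size=3)
            psi *= model.L2 / np.linalg.norm(psi)
            p8 = rng.normal(size=3) * 100
            got_v = humerus_angles_vector(humerus_pointset(model, p8, p8 - psi))
            got_p = humerus_angles_psi(HumerusProjection(*psi))
            for a, b in zip(got_v, got_p):
                if math.isfinite(a) or math.isfinite(b):
                    assert a == pytest.approx(b, abs=1e-8)


class TestElbowAngle:
    def test_straight_arm_is_zero(self, model):
        pts = PointSet({8: np.array([0.0, 2.0, 0.0]), 9: np.array([0.0, 1.0, 0.0]),
                        10: np.zeros(3)})
        assert elbow_angle(pts) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle(self, model):
        pts = PointSet({8: np.array([0.0, 2.0, 0.0]), 9: np.array([0.0, 1.0, 0.0]),
                        10: np.array([1.0, 1.0, 0.0])})
        assert elbow_angle(pts) == pytest.approx(90.0, abs=1e-9)

    def test_fully_folded_limit(self, model):
        pts = PointSet({8: np.array([0.0, 2.0, 0.0]), 9: np.array([0.0, 1.0, 0.0]),
                        10: np.array([0.0, 2.0, 0.0])})
        assert elbow_angle(pts) == pytest.approx(180.0, abs=1e-9)

    def test_monotone_in_flexion_sweep(self, model):
        p8, p9 = np.array([0.0, 2.0, 0.0]), np.array([0.0, 1.0, 0.0])
        prev = -1.0
        for phi in np.linspace(0.0, 179.0, 60):
            # P10 sweeps a circle around P9 from extension toward flexion
            a = math.radians(phi)
            p10 = p9 + np.array([math.sin(a), -math.cos(a), 0.0])
            th = elbow_angle(PointSet({8: p8, 9: p9, 10: p10}))
            assert th > prev
            prev = th


class TestWristAngles:
    def _pts(self, p13):
        return PointSet(
            {
                10: np.zeros(3),
                11: np.array([0.0, 0.0, 1.0]),
                12: np.array([1.0, 0.0, 0.0]),
                13: np.asarray(p13, dtype=float),
            }
        )

    def test_neutral_metacarpal_is_zero(self):
        assert wrist_angles(self._pts([0.0, -1.0, 0.0])) == pytest.approx(
            (0.0, 0.0), abs=1e-9
        )

    def test_metacarpal_on_reference_is_ninety(self):
        t7, _ = wrist_angles(self._pts([0.0, 0.0, 1.0]))
        assert t7 == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("phi", [10, 25, 40, 55, 70, 80])
    def test_flexion_chord_identity(self, phi):
        a = math.radians(phi)
        m = math.sin(a) * np.array([0.0, 0.0, 1.0]) - math.cos(a) * np.array([0.0, 1.0, 0.0])
        t7, _ = wrist_angles(self._pts(m))
        assert t7 == pytest.approx(phi, abs=1e-9)


class TestHumeralCategory:
    @pytest.mark.parametrize(
        "t4,t5,expected",
        [
            (30.0, 80.0, "sagittal_XY"),
            (80.0, 30.0, "frontal_YZ"),
            (45.0, 45.0, "frontal_YZ"),
            (math.nan, 45.0, "undetermined"),
        ],
    )
    def test_rule(self, t4, t5, expected):
        assert humeral_category(t4, t5) == expected


class TestExtractPose:
    def test_rest_pose_all_zero_except_theta5(self, model):
        local = forward_pose({}, model)
        pose = extract_pose(marker_dict(local), model, markers_are_local=True)
        assert pose.theta["theta5"] == pytest.approx(90.0, abs=1e-9)
        assert pose.validity["theta3"] == "degenerate_denominator"
        for lab in ("theta1", "theta2", "theta4", "theta6", "theta7", "theta8"):
            assert pose.theta[lab] == pytest.approx(0.0, abs=1e-9)

    def test_missing_marker_named(self, model):
        local = forward_pose({}, model)
        mk = marker_dict(local)
        mk.pop("M10")
        with pytest.raises(MissingMarkerError, match="M10"):
            extract_pose(mk, model, markers_are_local=True)

    def test_not_requested_flagging(self, model):
        local = forward_pose({}, model)
        pose = extract_pose(marker_dict(local), model, wanted=["theta6"], markers_are_local=True)
        assert pose.validity["theta6"] == "ok"
        assert pose.validity["theta1"] == "not_requested"
        assert math.isnan(pose.theta["theta1"])

    def test_rigid_world_placement_invariance(self, model, random_local_poses):
        """Angles are unchanged by where the subject stands in the world frame."""
        (_, local), = random_local_poses(1)
        base = extract_pose(marker_dict(local), model, markers_are_local=True)
        for alpha, beta, gamma in ((57.0, 0.0, 90.0), (-120.0, 10.0, 70.0)):
            t_true = EulerTransform(alpha, beta, gamma, np.array([40.0, -900.0, 310.0]))
            world = {k: t_true.to_world(v) for k, v in local.items()}
            # re-solve alpha from a rest calibration frame placed by the same transform
            rest = forward_pose({}, model)
            t_solved = build_transform(
                Point3.from_array(t_true.to_world(rest[3]), "world"),
                Point3.from_array(t_true.to_world(rest[4]), "world"),
                beta,
                gamma,
                model,
            )
            pose = extract_pose(marker_dict(world), model, t_solved)
            for lab in ANGLE_LABELS:
                a, b = base.theta[lab], pose.theta[lab]
                if math.isfinite(a) or math.isfinite(b):
                    assert a == pytest.approx(b, abs=1e-8)

    def test_scale_invariance(self, model, random_local_poses):
        (_, local), = random_local_poses(1)
        base = extract_pose(marker_dict(local), model, markers_are_local=True)
        big_model = default_model(model.lengths * 2.5)
        scaled = {k: 2.5 * v for k, v in local.items()}
        pose = extract_pose(marker_dict(scaled), big_model, markers_are_local=True)
        for lab in ANGLE_LABELS:
            a, b = base.theta[lab], pose.theta[lab]
            if math.isfinite(a) or math.isfinite(b):
                assert a == pytest.approx(b, abs=1e-9)
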