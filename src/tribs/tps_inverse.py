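"""Inverse solving of joint angles from TPS quantities.

For the clavicle, forearm and metacarpal the defining triangles are isosceles
with known leg lengths, so the triangle area determines the sine of the
spatial vertex angle: |S| = ½L_h²·sin(vertex) for segments 1 and 4 and
½L2·L3·sin(vertex) for the forearm.  The sine branch is resolved per angle:
the clavicle and wrist motion angles are the complement of the vertex angle
(rest triangles have maximal area), restricted to the anatomically plausible
branch below 90° excursion; the elbow angle is disambiguated with the
law-of-cosines sign.  The three glenohumeral angles are recovered exactly,
with direction, from the signed humerus TPS determinants:
ψ1 = −2M₃/L2, ψ2 = −2U₄/L2, ψ3 = 2N₅/L2.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import GeometryError
from .euclidean_angles import (
    HumerusProjection,
    PoseAngles,
    _coerce_markers,
    humerus_angles_psi,
)
from .model import ANGLE_LABELS, LimbModel, normalize_angle_label
from .tps import TPSPoint, projected_areas, triangle_area, triangle_from_spec, tps_point
from .virtual_points import build_point_set


def _leg_product(segment_id: int, model: LimbModel) -> float:
    if segment_id in (1, 4):
        return model.length_of(segment_id) ** 2
    if segment_id == 3:
        return model.L2 * model.L3
    raise GeometryError(
        f"area inversion applies to segments 1, 3, 4, not {segment_id}"
    )


def angle_from_area(
    area: float, segment_id: int, model: LimbModel
) -> tuple[float, bool]:
    """Sine-branch vertex angle of an isosceles defining triangle.

    Returns ``(theta_deg, ambiguous)`` with θ on the principal branch
    [0°, 90°]; ``ambiguous`` is True whenever the sine cannot distinguish θ
    from 180° − θ (i.e. for every θ < 90°).
    """
    if area < 0:
        raise GeometryError("triangle area cannot be negative")
    legs = _leg_product(segment_id, model)
    s = 2.0 * area / legs
    if s > 1.0 + 1e-9:
        raise GeometryError(
            f"area {area:.6g} mm^2 exceeds the maximum {0.5 * legs:.6g} mm^2 "
            f"for segment {segment_id}"
        )
    theta = math.degrees(math.asin(min(1.0, s)))
    return theta, theta < 90.0


def humerus_psi_from_tps(
    tps_pts: list[TPSPoint], model: LimbModel
) -> HumerusProjection:
    """Humerus axis differences ψ from the three signed humerus TPS points.

    ``tps_pts`` holds the TPS images of the humerus triangles in table order
    (reference P5, P6, P7).  Uses ψ1 = −2M₃/L2, ψ2 = −2U₄/L2, ψ3 = 2N₅/L2.
    A recovered |ψ| off the humerus length by more than 5% warns (noise);
    beyond 20% it is an error.
    """
    if len(tps_pts) != 3:
        raise GeometryError("expected the three humerus TPS points")
    L2 = model.L2
    psi = HumerusProjection(
        psi1=-2.0 * tps_pts[0].m / L2,
        psi2=-2.0 * tps_pts[1].u / L2,
        psi3=2.0 * tps_pts[2].n / L2,
    )
    norm = float(np.linalg.norm(psi.as_array))
    rel = abs(norm - L2) / L2
    if rel > 0.20:
        raise GeometryError(
            f"|psi| = {norm:.3f} mm deviates from L2 = {L2:.3f} mm by "
            f"{100 * rel:.1f}%"
        )
    if rel > 0.05:
        warnings.warn(
            f"|psi| deviates from L2 by {100 * rel:.1f}% (noisy markers?)",
            stacklevel=2,
        )
    return psi


def angles_via_tps(
    markers,
    model: LimbModel,
    transform=None,
    wanted=None,
    *,
    markers_are_local: bool = False,
) -> PoseAngles:
    """Full TPS-route angle extraction for one frame.

    Mirrors :func:`tribs.euclidean_angles.extract_pose` but goes through
    triangle areas and signed TPS coordinates; agrees with the Euclidean
    route wherever both are defined and the branch is unambiguous.
    """
    pts_w = _coerce_markers(markers)
    if markers_are_local:
        local = pts_w
    else:
        if transform is None:
            raise GeometryError("transform required for world-frame markers")
        local = {pid: transform.to_local(p) for pid, p in pts_w.items()}
    pset = build_point_set(local, model)
    wanted_labels = (
        set(ANGLE_LABELS)
        if wanted is None
        else {normalize_angle_label(a) for a in wanted}
    )
    pose = PoseAngles()

    seg_areas: dict[str, float] = {}
    humerus_points: list[TPSPoint] = []
    for seg in model.segment_table:
        for tri in seg.triangles:
            pa = projected_areas(triangle_from_spec(pset, tri))
            seg_areas[tri.angle_label] = triangle_area(pa)
            if seg.segment_id == 2:
                humerus_points.append(tps_point(pa))

    def vertex_angle(label: str, apex: int, leg_i: int, leg_j: int) -> tuple[float, bool]:
        # invert against the measured leg lengths: sin(vertex) <= 1 holds by
        # construction even for noisy markers (model lengths would not)
        la = float(np.linalg.norm(pset[leg_i] - pset[apex]))
        lb = float(np.linalg.norm(pset[leg_j] - pset[apex]))
        if la * lb < 1e-18:
            raise GeometryError(f"degenerate triangle legs for {label}")
        s = 2.0 * seg_areas[label] / (la * lb)
        theta = math.degrees(math.asin(min(1.0, s)))
        return theta, theta < 90.0

    # clavicle and wrist: motion angle is the complement of the vertex angle
    for label, apex, li, lj in (
        ("theta1", 3, 1, 4),
        ("theta2", 3, 2, 4),
        ("theta7", 10, 11, 13),
        ("theta8", 10, 12, 13),
    ):
        if label in wanted_labels:
            vertex, ambiguous = vertex_angle(label, apex, li, lj)
            pose.set(label, 90.0 - vertex)
            pose.branch_ambiguous[label] = ambiguous

    if {"theta3", "theta4", "theta5"} & wanted_labels:
        psi = humerus_psi_from_tps(humerus_points, model)
        t3, t4, t5 = humerus_angles_psi(psi)
        for lab, val in (("theta3", t3), ("theta4", t4), ("theta5", t5)):
            if lab in wanted_labels:
                pose.set(lab, val)

    if "theta6" in wanted_labels:
        vertex, ambiguous = vertex_angle("theta6", 9, 8, 10)
        # law-of-cosines sign at the elbow picks the branch
        p8, p9, p10 = pset[8], pset[9], pset[10]
        cos_num = (
            np.dot(p8 - p9, p8 - p9)
            + np.dot(p10 - p9, p10 - p9)
            - np.dot(p8 - p10, p8 - p10)
        )
        theta6 = vertex if cos_num < 0 else 180.0 - vertex
        pose.set("theta6", theta6)
        pose.branch_ambiguous["theta6"] = False
    return pose
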