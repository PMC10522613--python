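"""Euclidean-space extraction of the eight joint angles from a point set.

The clavicle, elbow and wrist angles come from arc-cosines of coordinate
ratios and chord lengths; the three glenohumeral angles are projection-plane
angles of the humerus axis, computed either from cross-product normals of the
defining triangles (`humerus_angles_vector`) or directly from the coordinate
differences ψ = P8 − P9 (`humerus_angles_psi`).  The two humerus routes are
algebraically identical; both are kept because the cross-product form is the
geometric definition while the ψ form is the cheap closed form the inverse
solver also uses.

Angles are reported in degrees.  Projection angles have intrinsic degenerate
configurations (e.g. θ3 is undefined for a vertical humerus); degenerate
entries are returned as NaN and flagged rather than silently zeroed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, MissingMarkerError
from .model import ANGLE_LABELS, LimbModel, Point3, normalize_angle_label
from .virtual_points import PointSet, build_point_set

#: relative excess of |arccos argument| over 1 treated as floating-point noise
CLAMP_SILENT = 1e-9
#: relative excess treated as tolerable geometry noise (clamped with warning)
CLAMP_WARN = 1e-3
#: relative cross-product / denominator norm below which a projection angle is
#: undefined
DEGENERATE_TOL = 1e-9


@dataclass
class HumerusProjection:
    """Coordinate differences of the humerus axis: ψ = P8 − P9 (mm)."""

    psi1: float
    psi2: float
    psi3: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.psi1, self.psi2, self.psi3])


@dataclass
class PoseAngles:
    """θ1..θ8 in degrees with per-angle validity and the humeral category.

    ``theta[label]`` is NaN when the angle is undefined or was not requested;
    ``validity[label]`` is one of ``ok``, ``degenerate_denominator``,
    ``not_requested``.
    """

    theta: dict[str, float] = field(
        default_factory=lambda: {lab: math.nan for lab in ANGLE_LABELS}
    )
    validity: dict[str, str] = field(
        default_factory=lambda: {lab: "not_requested" for lab in ANGLE_LABELS}
    )
    humeral_category: str = "undetermined"
    #: set by the TPS route: True where only a sine branch was recoverable
    branch_ambiguous: dict[str, bool] = field(default_factory=dict)

    def set(self, label: str, value: float) -> None:
        self.theta[label] = value
        self.validity[label] = "ok" if math.isfinite(value) else "degenerate_denominator"

    def __getitem__(self, label) -> float:
        return self.theta[normalize_angle_label(label)]


def _safe_arccos_deg(arg: float) -> float:
    """arccos in degrees with a graded out-of-range policy."""
    excess = abs(arg) - 1.0
    if excess > CLAMP_WARN:
        raise GeometryError(f"arccos argument {arg!r} out of range beyond tolerance")
    if excess > CLAMP_SILENT:
        warnings.warn(f"arccos argument {arg:.9f} clamped to [-1, 1]", stacklevel=3)
    return math.degrees(math.acos(min(1.0, max(-1.0, arg))))


def clavicle_angles(pts: PointSet) -> tuple[float, float]:
    """Sternoclavicular elevation θ1 and protraction θ2.

    θ1 = 90° − arccos(y4 / y1); θ2 = 90° − arccos((x2·x4 + z2·z4) / y1²),
    where P1 and P2 are the fixed clavicle references.
    """
    p1, p2, p4 = pts[1], pts[2], pts[4]
    y1 = p1[1]
    theta1 = 90.0 - _safe_arccos_deg(p4[1] / y1)
    theta2 = 90.0 - _safe_arccos_deg((p2[0] * p4[0] + p2[2] * p4[2]) / y1**2)
    return theta1, theta2


def humerus_angles_psi(psi: HumerusProjection) -> tuple[float, float, float]:
    """Glenohumeral projection angles from ψ = P8 − P9.

    θ3 = arccos(−ψ1/√(ψ3²+ψ1²)), θ4 = arccos(ψ2/√(ψ2²+ψ1²)),
    θ5 = arccos(ψ3/√(ψ2²+ψ3²)).  An angle whose denominator nearly vanishes
    is returned as NaN.  θ5 is 90° in the rest pose by this convention.
    """
    p1, p2, p3 = psi.psi1, psi.psi2, psi.psi3
    scale = math.sqrt(p1 * p1 + p2 * p2 + p3 * p3)
    if scale < 1e-12:
        raise GeometryError("degenerate humerus: |P8 - P9| = 0")
    out = []
    for num, a, b in ((-p1, p3, p1), (p2, p2, p1), (p3, p2, p3)):
        denom = math.hypot(a, b)
        if denom < DEGENERATE_TOL * scale:
            out.append(math.nan)
        else:
            out.append(_safe_arccos_deg(num / denom))
    if all(math.isnan(v) for v in out):
        raise GeometryError("all three humerus projection angles are degenerate")
    return tuple(out)


def humerus_angles_vector(pts: PointSet) -> tuple[float, float, float]:
    """Glenohumeral angles from the normals of the three humerus triangles.

    𝓐 = L⃗9,8 × L⃗9,5, 𝓑 = L⃗9,8 × L⃗9,6, 𝓒 = L⃗9,8 × L⃗9,7; the angles are
    measured against the fixed reference legs P8→P6 (for θ3), P8→P7 (θ4) and
    P8→P5 (θ5), which aligns this route with `humerus_angles_psi` for every
    pose.
    """
    p5, p6, p7, p8, p9 = pts[5], pts[6], pts[7], pts[8], pts[9]
    axis = p8 - p9
    scale2 = float(np.dot(axis, axis))
    if scale2 < 1e-18:
        raise GeometryError("degenerate humerus: |P8 - P9| = 0")
    normal_a = np.cross(axis, p5 - p9)
    normal_b = np.cross(axis, p6 - p9)
    normal_c = np.cross(axis, p7 - p9)
    legs = (p8 - p6, p7 - p8, p5 - p8)  # references for theta3, theta4, theta5
    out = []
    for n, leg in zip((normal_a, normal_b, normal_c), legs):
        nn = float(np.linalg.norm(n))
        ll = float(np.linalg.norm(leg))
        if nn < DEGENERATE_TOL * math.sqrt(scale2) * ll:
            out.append(math.nan)
        else:
            out.append(_safe_arccos_deg(float(np.dot(n, leg)) / (nn * ll)))
    return tuple(out)


def elbow_angle(pts: PointSet) -> float:
    """Elbow flexion by the law of cosines: 0° = straight arm.

    θ6 = 180° − arccos((l8,9² + l9,10² − l8,10²) / (2 l8,9 l9,10)).
    """
    p8, p9, p10 = pts[8], pts[9], pts[10]
    l89 = float(np.linalg.norm(p8 - p9))
    l910 = float(np.linalg.norm(p9 - p10))
    if l89 < 1e-9 or l910 < 1e-9:
        raise GeometryError("degenerate elbow: zero-length humerus or forearm")
    l810 = float(np.linalg.norm(p8 - p10))
    arg = (l89**2 + l910**2 - l810**2) / (2.0 * l89 * l910)
    return 180.0 - _safe_arccos_deg(arg)


def wrist_angles(pts: PointSet) -> tuple[float, float]:
    """Wrist flexion angles toward the P11 (θ7) and P12 (θ8) references.

    θ7 = 90° − arccos(1 − l11,13²/(2 l10,13²)) and likewise for θ8 with P12.
    Positive angles bend the metacarpal toward the reference point; the sign
    goes negative when it bends away.
    """
    p10, p11, p12, p13 = pts[10], pts[11], pts[12], pts[13]
    l2 = float(np.dot(p13 - p10, p13 - p10))
    if l2 < 1e-18:
        raise GeometryError("degenerate metacarpal: P13 coincides with P10")
    theta7 = 90.0 - _safe_arccos_deg(1.0 - float(np.dot(p11 - p13, p11 - p13)) / (2.0 * l2))
    theta8 = 90.0 - _safe_arccos_deg(1.0 - float(np.dot(p12 - p13, p12 - p13)) / (2.0 * l2))
    return theta7, theta8


def humeral_category(theta4_initial: float, theta5_initial: float) -> str:
    """Classify the humeral motion from its initial angles.

    θ4 < θ5 selects the sagittal (X-Y) decomposition, otherwise the frontal
    (Y-Z) one; undefined inputs give ``undetermined``.
    """
    if not (math.isfinite(theta4_initial) and math.isfinite(theta5_initial)):
        return "undetermined"
    return "sagittal_XY" if theta4_initial < theta5_initial else "frontal_YZ"


_MARKER_IDS = (3, 4, 8, 9, 10, 13)


def _coerce_markers(markers) -> dict[int, np.ndarray]:
    """Accept {3: xyz} or {"M3": xyz} mappings with array or Point3 values."""
    out: dict[int, np.ndarray] = {}
    for key, val in markers.items():
        pid = int(str(key).removeprefix("M"))
        out[pid] = val.xyz if isinstance(val, Point3) else np.asarray(val, dtype=float)
    missing = [f"M{i}" for i in _MARKER_IDS if i not in out]
    if missing:
        raise MissingMarkerError(f"missing marker(s): {', '.join(missing)}")
    bad = [f"M{i}" for i in _MARKER_IDS if not np.all(np.isfinite(out[i]))]
    if bad:
        raise MissingMarkerError(f"non-finite marker(s): {', '.join(bad)}")
    return out


def extract_pose(
    markers,
    model: LimbModel,
    transform=None,
    wanted=None,
    *,
    markers_are_local: bool = False,
) -> PoseAngles:
    """Full Euclidean-route angle extraction for one frame.

    ``markers`` maps marker ids (3, 4, 8, 9, 10, 13, or names ``"M3"``...)
    to world-frame coordinates; they are moved into the local frame with
    ``transform`` (already-local input may set ``markers_are_local``), the
    virtual points are constructed, and the requested angles computed.
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
    if {"theta1", "theta2"} & wanted_labels:
        t1, t2 = clavicle_angles(pset)
        if "theta1" in wanted_labels:
            pose.set("theta1", t1)
        if "theta2" in wanted_labels:
            pose.set("theta2", t2)
    if {"theta3", "theta4", "theta5"} & wanted_labels:
        t3, t4, t5 = humerus_angles_vector(pset)
        for lab, val in (("theta3", t3), ("theta4", t4), ("theta5", t5)):
            if lab in wanted_labels:
                pose.set(lab, val)
    if "theta6" in wanted_labels:
        pose.set("theta6", elbow_angle(pset))
    if {"theta7", "theta8"} & wanted_labels:
        t7, t8 = wrist_angles(pset)
        if "theta7" in wanted_labels:
            pose.set("theta7", t7)
        if "theta8" in wanted_labels:
            pose.set("theta8", t8)
    return pose
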