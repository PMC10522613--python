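"""Construction of the virtual reference points (1, 2, 5, 6, 7, 11, 12).

All geometry here lives in the local frame (origin at the sternoclavicular
joint, point 3) and uses plain ``numpy`` 3-vectors in millimetres.

The clavicle references P1/P2 are fixed in the local frame; the humerus
references P5/P6/P7 ride with the glenohumeral marker P8 along the +Y, +Z and
+X axes; the hand references P11/P12 solve a small constrained system: each is
perpendicular to the forearm through the wrist, at metacarpal distance from
the wrist, with one coordinate pinned (y for P11, x for P12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

from .errors import GeometryError
from .model import (
    ACTUAL_POINT_IDS,
    FIXED_POINT_IDS,
    VIRTUAL_POINT_IDS,
    LimbModel,
)

#: relative threshold on |y9 − y10| / l9,10 above which the forearm counts as
#: vertical and the singular-pose convention is used
VERTICAL_FOREARM_TOL = 1e-6


def clavicle_refs(model: LimbModel) -> tuple[np.ndarray, np.ndarray]:
    """Fixed clavicle reference points.

    P1 sits on the +Y axis at clavicle length (so θ1 = 0 for a horizontal
    clavicle); P2 is horizontal and perpendicular to the rest clavicle
    direction (so θ2 = 0 at rest), also at clavicle length.
    """
    phi = math.radians(model.clavicle_offset_deg)
    p1 = np.array([0.0, model.L1, 0.0])
    p2 = np.array([math.cos(phi) * model.L1, 0.0, math.sin(phi) * model.L1])
    return p1, p2


def humerus_refs(p8: np.ndarray, model: LimbModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Humerus reference points P5, P6, P7 at humerus length from P8.

    The legs P8→P5, P8→P6, P8→P7 lie along the +Y, +Z and +X axes, making
    them normals of the X-Z, X-Y and Y-Z planes.  The positive directions are
    fixed globally so that the three projection-plane angle formulas and the
    signed-area inverse agree for every pose.
    """
    p8 = np.asarray(p8, dtype=float)
    if not np.all(np.isfinite(p8)):
        raise GeometryError("P8 must be finite")
    L2 = model.L2
    return (
        p8 + np.array([0.0, L2, 0.0]),
        p8 + np.array([0.0, 0.0, L2]),
        p8 + np.array([L2, 0.0, 0.0]),
    )


def hand_ref_dirs(p9: np.ndarray, p10: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit offset directions of P11 and P12 from the wrist P10.

    Encapsulates the pin/branch rule shared by :func:`hand_refs` and the
    forward-kinematics generator: each direction is perpendicular to the
    forearm, P11's has zero y component, P12's zero x component, and the
    branch with positive z (positive remaining coordinate at exact zero) is
    selected.  A vertical forearm returns the singular-pose conventions
    (+z for P11, +x for P12).
    """
    p9 = np.asarray(p9, dtype=float)
    p10 = np.asarray(p10, dtype=float)
    u = p9 - p10
    lu = float(np.linalg.norm(u))
    if lu < 1e-9:
        raise GeometryError("degenerate forearm: P9 coincides with P10")
    if abs(u[1]) >= (1.0 - VERTICAL_FOREARM_TOL) * lu:
        return np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])

    h = math.hypot(u[0], u[2])
    q11 = np.array([-u[2], 0.0, u[0]]) / h
    s = math.copysign(1.0, q11[2]) if q11[2] != 0.0 else math.copysign(1.0, q11[0])
    q11 *= s

    h = math.hypot(u[1], u[2])
    if h < 1e-9 * lu:
        # forearm along +/-X: the x-pinned system is underdetermined; take the
        # continuous limit of the selected branch, +Z
        q12 = np.array([0.0, 0.0, 1.0])
    else:
        q12 = np.array([0.0, -u[2], u[1]]) / h
        s = math.copysign(1.0, q12[2]) if q12[2] != 0.0 else math.copysign(1.0, q12[1])
        q12 *= s
    return q11, q12


def hand_refs(
    p9: np.ndarray, p10: np.ndarray, p13: np.ndarray, model: LimbModel
) -> tuple[np.ndarray, np.ndarray]:
    """Hand reference points P11 and P12.

    Both are perpendicular to the forearm vector through the wrist P10 at
    distance l10,13; P11 has its y coordinate pinned to y10, P12 its x
    coordinate pinned to x10.  Of the two algebraic solutions the branch with
    positive z offset is returned (positive remaining coordinate when the z
    offset is exactly zero).  A vertical forearm makes the system singular;
    the conventional values P11 = P10 + (0, 0, l) and P12 = P10 + (l, 0, 0)
    are returned there.
    """
    p10 = np.asarray(p10, dtype=float)
    p13 = np.asarray(p13, dtype=float)
    l = float(np.linalg.norm(p13 - p10))
    if l < 1e-9:
        raise GeometryError("degenerate metacarpal: P13 coincides with P10")
    q11, q12 = hand_ref_dirs(p9, p10)
    return p10 + l * q11, p10 + l * q12


@dataclass
class PointSet:
    """All thirteen local-frame points of one pose, with provenance."""

    points: dict[int, np.ndarray]
    provenance: dict[int, str] = field(default_factory=dict)

    def __getitem__(self, point_id: int) -> np.ndarray:
        return self.points[point_id]

    def __contains__(self, point_id: int) -> bool:
        return point_id in self.points

    def check(self, rel_tol: float = 1e-8) -> None:
        """Assert the defining geometric constraints of the virtual points."""
        p9, p10, p13 = self[9], self[10], self[13]
        l = np.linalg.norm(p13 - p10)
        for pid in (11, 12):
            leg = np.linalg.norm(self[pid] - p10)
            if abs(leg - l) > rel_tol * l:
                raise GeometryError(f"P{pid} leg length violates |P{pid}-P10| = l10,13")
            dot = abs(np.dot(self[pid] - p10, p9 - p10))
            if dot > rel_tol * l * np.linalg.norm(p9 - p10):
                raise GeometryError(f"P{pid} is not perpendicular to the forearm")


def build_point_set(measured: dict[int, np.ndarray], model: LimbModel) -> PointSet:
    """Assemble the full 13-point set from the six measured local points."""
    missing = sorted(ACTUAL_POINT_IDS - measured.keys())
    if missing:
        raise GeometryError(f"missing measured points: {missing}")
    pts: dict[int, np.ndarray] = {
        pid: np.asarray(measured[pid], dtype=float) for pid in ACTUAL_POINT_IDS
    }
    pts[1], pts[2] = clavicle_refs(model)
    pts[5], pts[6], pts[7] = humerus_refs(pts[8], model)
    pts[11], pts[12] = hand_refs(pts[9], pts[10], pts[13], model)
    provenance = {pid: "measured" for pid in ACTUAL_POINT_IDS}
    provenance.update({pid: "fixed" for pid in FIXED_POINT_IDS})
    provenance.update({pid: "virtual" for pid in VIRTUAL_POINT_IDS})
    return PointSet(points=pts, provenance=provenance)
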