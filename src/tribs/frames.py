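"""World ↔ local coordinate transformation.

The local frame has its origin at the sternoclavicular marker (point 3) and is
related to the world frame by a Z-Y-X Euler rotation (angles α, β, γ about the
world Z, Y, X axes) plus the translation to point 3.  β and γ are known from
how the capture volume's world frame was set up; the azimuth α is recovered
numerically from a calibration frame using the known rest position of the
acromioclavicular marker (point 4) in the local frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FrameTagError, InconsistentMarkerError, SolverError
from .model import LimbModel, Point3


def build_rotation(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Z-Y-X Euler rotation matrix R = Rz(α) · Ry(β) · Rx(γ)."""
    ca, sa = math.cos(math.radians(alpha_deg)), math.sin(math.radians(alpha_deg))
    cb, sb = math.cos(math.radians(beta_deg)), math.sin(math.radians(beta_deg))
    cg, sg = math.cos(math.radians(gamma_deg)), math.sin(math.radians(gamma_deg))
    return np.array(
        [
            [ca * cb, ca * sb * sg - sa * cg, ca * sb * cg + sa * sg],
            [sa * cb, sa * sb * sg + ca * cg, sa * sb * cg - ca * sg],
            [-sb, cb * sg, cb * cg],
        ]
    )


def rest_local_p4(model: LimbModel) -> Point3:
    """Rest-pose local coordinates of point 4: (−sin φ·L1, 0, cos φ·L1).

    φ is the clavicle offset from the frontal plane (default 20°); the rest
    clavicle is horizontal, so the y coordinate is zero.
    """
    phi = math.radians(model.clavicle_offset_deg)
    return Point3(-math.sin(phi) * model.L1, 0.0, math.cos(phi) * model.L1, "local")


@dataclass(frozen=True)
class EulerTransform:
    """A fully determined world→local transform (rotation cached)."""

    alpha_deg: float
    beta_deg: float
    gamma_deg: float
    p_lorg: np.ndarray  # world coordinates of point 3
    rotation: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "p_lorg", np.asarray(self.p_lorg, dtype=float).reshape(3)
        )
        R = build_rotation(self.alpha_deg, self.beta_deg, self.gamma_deg)
        object.__setattr__(self, "rotation", R)
        if abs(abs(math.sin(math.radians(self.beta_deg))) - 1.0) < 1e-6:
            warnings.warn(
                "intermediate Euler axis near 90 deg (gimbal lock); "
                "re-orient the world frame to avoid |beta| = 90 deg",
                stacklevel=2,
            )

    def to_local(self, points_world: np.ndarray) -> np.ndarray:
        """Apply R⁻¹ (P − P_LORG) to an (..., 3) array of world coordinates."""
        p = np.asarray(points_world, dtype=float)
        return (p - self.p_lorg) @ self.rotation

    def to_world(self, points_local: np.ndarray) -> np.ndarray:
        p = np.asarray(points_local, dtype=float)
        return p @ self.rotation.T + self.p_lorg


def solve_alpha(
    p3_world: Point3,
    p4_world: Point3,
    beta_deg: float,
    gamma_deg: float,
    model: LimbModel,
    length_tol: float = 0.05,
    consistency_tol: float = 0.15,
) -> float:
    """Recover the world-frame azimuth α from a calibration (near-rest) frame.

    The clavicle marker pair must be consistent with the model
    (| |P4−P3| − L1 | ≤ ``length_tol``·L1).  The scalar α is found by
    minimizing the Euclidean residual of the forward transform of the known
    rest-pose local point 4; an analytic azimuth estimate seeds a
    trust-region least-squares polish.  Returns α in degrees in (−180, 180].
    """
    if p3_world.frame_tag != "world" or p4_world.frame_tag != "world":
        raise FrameTagError("solve_alpha expects world-frame points")
    w = p4_world - p3_world
    clav = float(np.linalg.norm(w))
    if abs(clav - model.L1) > length_tol * model.L1:
        raise InconsistentMarkerError(
            f"|P4-P3| = {clav:.3f} mm differs from L1 = {model.L1:.3f} mm "
            f"by more than {100 * length_tol:.0f}%"
        )
    v = build_rotation(0.0, beta_deg, gamma_deg) @ rest_local_p4(model).xyz

    def residual(alpha):
        return build_rotation(float(alpha[0]), beta_deg, gamma_deg) @ rest_local_p4(
            model
        ).xyz - w

    # analytic seed: Rz only changes the x-y components
    if math.hypot(v[0], v[1]) < 1e-12 * model.L1 or math.hypot(w[0], w[1]) < 1e-12 * model.L1:
        raise SolverError(
            "alpha is unobservable: clavicle direction parallel to world Z axis"
        )
    alpha0 = math.degrees(math.atan2(w[1], w[0]) - math.atan2(v[1], v[0]))
    sol = least_squares(residual, x0=[alpha0], method="lm")
    alpha = float(sol.x[0]) % 360.0
    if alpha > 180.0:
        alpha -= 360.0
    r = np.asarray(residual([alpha]))
    res = float(np.linalg.norm(r))
    # split the residual: the component a rotation about Z can still reduce
    # (tangential, perpendicular to the horizontal target direction) must be
    # at solver precision; the irreducible remainder reflects how far the
    # calibration frame is from the modeled rest clavicle and is bounded by
    # the same marker-consistency tolerance as the length precheck
    w_hat = np.array([w[0], w[1]]) / math.hypot(w[0], w[1])
    tangential = abs(-w_hat[1] * r[0] + w_hat[0] * r[1])
    if tangential > 1e-6 * model.L1:
        raise SolverError(
            f"alpha solve did not converge: tangential residual "
            f"{tangential:.3e} mm exceeds {1e-6 * model.L1:.3e} mm",
            residual=res,
        )
    if res > consistency_tol * model.L1:
        raise SolverError(
            f"calibration frame inconsistent with the rest clavicle pose: "
            f"residual {res:.3e} mm exceeds {consistency_tol * model.L1:.3e} mm",
            residual=res,
        )
    return alpha


def build_transform(
    p3_world: Point3,
    p4_world: Point3,
    beta_deg: float,
    gamma_deg: float,
    model: LimbModel,
) -> EulerTransform:
    """Solve α from a calibration frame and assemble the transform."""
    alpha = solve_alpha(p3_world, p4_world, beta_deg, gamma_deg, model)
    return EulerTransform(alpha, beta_deg, gamma_deg, p3_world.xyz)


def world_to_local(points_world, t: EulerTransform):
    """Transform world-frame points into the local frame.

    Accepts a single :class:`Point3`, an iterable of them, or a mapping
    id → :class:`Point3`; returns the same shape with ``frame_tag="local"``.
    """
    if isinstance(points_world, Point3):
        if points_world.frame_tag != "world":
            raise FrameTagError("expected world-tagged point")
        return Point3.from_array(t.to_local(points_world.xyz), "local")
    if isinstance(points_world, dict):
        return {k: world_to_local(p, t) for k, p in points_world.items()}
    return [world_to_local(p, t) for p in points_world]
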