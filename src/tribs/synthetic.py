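"""Forward-kinematics generator of synthetic marker trajectories.

Builds the six marker positions (sternoclavicular, acromioclavicular,
glenohumeral, elbow, wrist, third-metacarpal end) from commanded joint-angle
trajectories, so the whole extraction pipeline can be exercised and scored
without motion-capture hardware.  The construction inverts the defining
equations of each angle, so a noiseless single-DOF command is recovered
exactly by the extractor.  Under combined commands the projection-angle
definitions couple; the ground truth written alongside the markers is
therefore always the set of defining equations evaluated on the generated
noiseless geometry.

The glenohumeral marker is not kinematically chained to the clavicle in the
extraction model (the scapula decouples them); the generator still needs a
placement rule and uses a fixed offset from the acromioclavicular marker,
rotated with the clavicle.  This affects data generation only.

Default capture rate is 60 Hz; optional measurement noise is isotropic
i.i.d. Gaussian per marker coordinate in the world frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError
from .euclidean_angles import extract_pose
from .frames import EulerTransform
from .model import ANGLE_LABELS, MARKER_NAMES, LimbModel, normalize_angle_label
from .virtual_points import hand_ref_dirs


@dataclass(frozen=True)
class Waveform:
    """A named scalar trajectory in degrees.

    Kinds: ``constant`` (``value``); ``ramp`` (``start``→``end`` over the
    whole duration); ``sine`` (``mean`` + ``amplitude``·sin(2π·f·t + phase));
    ``keyframes`` (piecewise cosine-eased interpolation of (t, value) pairs,
    tiled cyclically when ``period`` is set).  Cosine easing keeps the
    commanded trajectories slope-continuous, which a moving-average filter
    tracks with far less bias than corner-ramp trajectories.
    """

    kind: str = "constant"
    value: float = 0.0
    start: float = 0.0
    end: float = 0.0
    mean: float = 0.0
    amplitude: float = 0.0
    frequency_hz: float = 1.0
    phase_deg: float = 0.0
    keyframes: tuple[tuple[float, float], ...] = ()
    period: float | None = None

    def sample(self, t: float, duration: float) -> float:
        if self.kind == "constant":
            return self.value
        if self.kind == "ramp":
            s = 0.0 if duration <= 0 else min(max(t / duration, 0.0), 1.0)
            return self.start + (self.end - self.start) * s
        if self.kind == "sine":
            return self.mean + self.amplitude * math.sin(
                2.0 * math.pi * self.frequency_hz * t + math.radians(self.phase_deg)
            )
        if self.kind == "keyframes":
            if len(self.keyframes) < 2:
                raise ConfigError("keyframes waveform needs at least two knots")
            tt = t % self.period if self.period else t
            ks = self.keyframes
            if tt <= ks[0][0]:
                return ks[0][1]
            for (t0, v0), (t1, v1) in zip(ks, ks[1:]):
                if tt <= t1:
                    s = (tt - t0) / (t1 - t0)
                    return v0 + (v1 - v0) * 0.5 * (1.0 - math.cos(math.pi * s))
            return ks[-1][1]
        raise ConfigError(f"unknown waveform kind {self.kind!r}")


def constant(value: float) -> Waveform:
    return Waveform("constant", value=value)


def ramp(start: float, end: float) -> Waveform:
    return Waveform("ramp", start=start, end=end)


def sine(mean: float, amplitude: float, frequency_hz: float, phase_deg: float = 0.0) -> Waveform:
    return Waveform(
        "sine", mean=mean, amplitude=amplitude, frequency_hz=frequency_hz, phase_deg=phase_deg
    )


def keyframes(knots, period: float | None = None) -> Waveform:
    return Waveform("keyframes", keyframes=tuple((float(t), float(v)) for t, v in knots), period=period)


@dataclass(frozen=True)
class MotionSpec:
    """A complete synthetic recording specification."""

    duration_s: float
    rate_hz: float = 60.0
    angles: dict[str, Waveform] = field(default_factory=dict)
    category: str = "frontal_YZ"  # humerus command parametrization
    alpha_deg: float = 0.0
    beta_deg: float = 0.0
    gamma_deg: float = 0.0
    p_lorg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0
    shoulder_offset: tuple[float, float, float] = (0.0, -50.0, 0.0)
    name: str = "custom"

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        object.__setattr__(
            self,
            "angles",
            {normalize_angle_label(k): v for k, v in self.angles.items()},
        )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    k = np.cross(a, b)
    c = float(np.dot(a, b))
    s2 = float(np.dot(k, k))
    if s2 < 1e-24:
        if c > 0:
            return np.eye(3)
        raise GeometryError("180-degree clavicle flip is outside the command range")
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + kx + kx @ kx * ((1.0 - c) / s2)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    k = axis / np.linalg.norm(axis)
    return (
        v * math.cos(a)
        + np.cross(k, v) * math.sin(a)
        + k * float(np.dot(k, v)) * (1.0 - math.cos(a))
    )


def _check_range(label: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise GeometryError(
            f"commanded {label} = {value:.3f} deg outside the generator's "
            f"valid range [{lo}, {hi}] deg"
        )


def _humerus_direction(angles: dict[str, float], category: str) -> np.ndarray:
    """Unit ψ = (P8 − P9)/L2 from the category's commanded angle pair."""
    t3 = math.radians(angles.get("theta3", 0.0))
    if category == "frontal_YZ":
        t4 = math.radians(angles.get("theta4", 0.0))
        _check_range("theta4", math.degrees(t4), 0.0, 90.0)
        _check_range("theta3", math.degrees(t3), 0.0, 179.0)
        denom = math.sqrt(math.sin(t4) ** 2 + (math.cos(t4) * math.cos(t3)) ** 2)
        if denom < 1e-12:
            raise GeometryError("degenerate humerus command (theta3/theta4)")
        s = math.sin(t4) / denom
        return np.array(
            [-s * math.cos(t3), math.sqrt(max(0.0, 1.0 - s * s)), s * math.sin(t3)]
        )
    if category == "sagittal_XY":
        t5 = math.radians(angles.get("theta5", 90.0))
        _check_range("theta5", math.degrees(t5), 0.0, 180.0)
        _check_range("theta3", math.degrees(t3), 1.0, 179.0)
        denom = math.sqrt(math.sin(t3) ** 2 + (math.cos(t3) * math.cos(t5)) ** 2)
        rho = math.sin(t3) / denom
        psi1 = -math.cos(t3) * math.cos(t5) * rho / math.sin(t3)
        return np.array([psi1, rho * math.sin(t5), rho * math.cos(t5)])
    raise ConfigError(f"unknown humerus category {category!r}")


def forward_pose(
    angles: dict,
    model: LimbModel,
    category: str = "frontal_YZ",
    shoulder_offset=(0.0, -50.0, 0.0),
) -> dict[int, np.ndarray]:
    """Local-frame marker positions for one commanded pose.

    ``angles`` maps angle labels to degrees; omitted angles take their rest
    values.  Commands outside a DOF's invertible range raise a
    :class:`~tribs.errors.GeometryError` naming the angle.
    """
    cmd = {normalize_angle_label(k): float(v) for k, v in angles.items()}
    phi = math.radians(model.clavicle_offset_deg)
    e1 = np.array([math.cos(phi), 0.0, math.sin(phi)])
    e2 = np.array([-math.sin(phi), 0.0, math.cos(phi)])

    t1 = cmd.get("theta1", 0.0)
    t2 = cmd.get("theta2", 0.0)
    _check_range("theta1", t1, -90.0, 90.0)
    _check_range("theta2", t2, -90.0, 90.0)
    a = model.L1 * math.sin(math.radians(t2))
    y4 = model.L1 * math.sin(math.radians(t1))
    rest2 = model.L1**2 - a * a - y4 * y4
    if rest2 < -1e-9 * model.L1**2:
        raise GeometryError("commanded theta1/theta2 pair exceeds the clavicle range")
    p3 = np.zeros(3)
    p4 = a * e1 + np.array([0.0, y4, 0.0]) + math.sqrt(max(0.0, rest2)) * e2

    r_clav = _rotation_between(e2, p4 / model.L1)
    p8 = p4 + r_clav @ np.asarray(shoulder_offset, dtype=float)

    psi = _humerus_direction(cmd, category)
    p9 = p8 - model.L2 * psi

    t6 = cmd.get("theta6", 0.0)
    _check_range("theta6", t6, 0.0, 179.0)
    d = -psi
    axis = np.array([0.0, 0.0, 1.0]) - d[2] * d
    if np.linalg.norm(axis) < 1e-9:
        axis = np.array([1.0, 0.0, 0.0]) - d[0] * d
    f = _rodrigues(d, axis, t6)
    p10 = p9 + model.L3 * f

    # wrist: only explicitly commanded angles are pinned; an uncommanded one
    # rides along (the two flexion references are not orthogonal in general,
    # so pinning both over-constrains the metacarpal direction)
    q11, q12 = hand_ref_dirs(p9, p10)
    has7, has8 = "theta7" in cmd, "theta8" in cmd
    t7, t8 = cmd.get("theta7", 0.0), cmd.get("theta8", 0.0)
    _check_range("theta7", t7, -90.0, 90.0)
    _check_range("theta8", t8, -90.0, 90.0)
    s7, s8 = math.sin(math.radians(t7)), math.sin(math.radians(t8))
    if has7 and has8:
        g = float(np.dot(q11, q12))
        det = 1.0 - g * g
        if abs(det) < 1e-12:
            if abs(s7 - s8) > 1e-12:
                raise GeometryError(
                    "theta7/theta8 cannot be commanded independently: the "
                    "wrist references coincide for this forearm direction"
                )
            w = s7 * q11
        else:
            w = ((s7 - g * s8) * q11 + (s8 - g * s7) * q12) / det
    elif has7:
        w = s7 * q11
    elif has8:
        w = s8 * q12
    else:
        w = np.zeros(3)
    wn2 = float(np.dot(w, w))
    if wn2 > 1.0 + 1e-12:
        raise GeometryError("commanded theta7/theta8 pair is outside the wrist range")
    m = w + math.sqrt(max(0.0, 1.0 - wn2)) * f
    p13 = p10 + model.L4 * m

    return {3: p3, 4: p4, 8: p8, 9: p9, 10: p10, 13: p13}


#: command ranges (deg) used by :func:`random_pose` to stay clear of the
#: projection-angle degeneracies and of infeasible clavicle/wrist pairs
RANDOM_POSE_RANGES = {
    "theta1": (2.0, 40.0),
    "theta2": (2.0, 40.0),
    "theta3": (5.0, 85.0),
    "theta4": (5.0, 85.0),
    "theta6": (5.0, 85.0),
    "theta7": (2.0, 40.0),
    "theta8": (2.0, 40.0),
}


def random_pose(
    rng: np.random.Generator,
    model: LimbModel,
    ranges: dict | None = None,
    max_tries: int = 100,
) -> tuple[dict[str, float], dict[int, np.ndarray]]:
    """Draw a random non-degenerate pose: (commands, local marker points).

    Commands are sampled uniformly inside ``ranges`` and rejected when the
    pose is infeasible (the wrist pair feasibility depends on the forearm
    direction); every accepted pose has all eight angles defined.
    """
    ranges = ranges or RANDOM_POSE_RANGES
    for _ in range(max_tries):
        cmd = {lab: float(rng.uniform(lo, hi)) for lab, (lo, hi) in ranges.items()}
        try:
            return cmd, forward_pose(cmd, model)
        except GeometryError:
            continue
    raise GeometryError(f"no feasible pose found in {max_tries} draws")


@dataclass(frozen=True)
class SimulationResult:
    """Marker trajectories plus ground truth and provenance metadata."""

    markers: pd.DataFrame  # frame, time, M3_x ... M13_z (world frame, mm)
    truth: pd.DataFrame  # frame, time, theta1..theta8 (+ cmd_*) in degrees
    meta: dict


def generate_motion(spec: MotionSpec, model: LimbModel) -> SimulationResult:
    """Simulate a recording: world-frame marker series plus truth angles.

    Truth angles are the defining equations evaluated on the noiseless
    geometry; commanded values are carried alongside as ``cmd_theta*``.
    Deterministic for a given seed.
    """
    n = max(1, int(round(spec.duration_s * spec.rate_hz)))
    times = np.arange(n) / spec.rate_hz
    transform = EulerTransform(
        spec.alpha_deg, spec.beta_deg, spec.gamma_deg, np.asarray(spec.p_lorg)
    )
    rng = np.random.default_rng(spec.seed)

    marker_rows = np.empty((n, 18))
    truth_rows = np.empty((n, 8))
    cmd_rows = np.full((n, 8), np.nan)
    for i, t in enumerate(times):
        cmd = {
            lab: wf.sample(float(t), spec.duration_s)
            for lab, wf in spec.angles.items()
        }
        local = forward_pose(cmd, model, spec.category, spec.shoulder_offset)
        pose = extract_pose(
            {f"M{pid}": p for pid, p in local.items()}, model, markers_are_local=True
        )
        truth_rows[i] = [pose.theta[lab] for lab in ANGLE_LABELS]
        for j, lab in enumerate(ANGLE_LABELS):
            if lab in cmd:
                cmd_rows[i, j] = cmd[lab]
        world = transform.to_world(np.vstack([local[pid] for pid in (3, 4, 8, 9, 10, 13)]))
        marker_rows[i] = world.reshape(-1)
    if spec.noise_sd > 0:
        marker_rows = marker_rows + rng.normal(0.0, spec.noise_sd, marker_rows.shape)

    mcols = [f"{m}_{ax}" for m in MARKER_NAMES for ax in "xyz"]
    markers = pd.DataFrame(marker_rows, columns=mcols)
    markers.insert(0, "time", times)
    markers.insert(0, "frame", np.arange(n))
    truth = pd.DataFrame(truth_rows, columns=list(ANGLE_LABELS))
    for j, lab in enumerate(ANGLE_LABELS):
        truth[f"cmd_{lab}"] = cmd_rows[:, j]
    truth.insert(0, "time", times)
    truth.insert(0, "frame", np.arange(n))
    meta = {
        "name": spec.name,
        "seed": spec.seed,
        "rate_hz": spec.rate_hz,
        "noise_sd": spec.noise_sd,
        "category": spec.category,
        "n_frames": n,
        "alpha_deg": spec.alpha_deg,
        "beta_deg": spec.beta_deg,
        "gamma_deg": spec.gamma_deg,
    }
    return SimulationResult(markers=markers, truth=truth, meta=meta)


def fig_sequence_preset(noise_sd: float = 0.0, seed: int = 0) -> MotionSpec:
    """Sequential continuous-motion protocol, two identical 8 s cycles.

    Per cycle: a forward humerus lift, an elbow bend, a humerus turn about
    the vertical axis, an inward wrist snap, then a return to the initial
    (non-rest) posture.  Amplitudes sit inside the ranges typical of such a
    protocol (humerus elevation ~36-80 deg, elbow up to ~85 deg, wrist snap
    to ~-45 deg); the initial posture is lifted so no projection angle is
    degenerate.
    """
    cycle = 8.0
    angles = {
        "theta1": keyframes([(0, 1), (0.5, 1), (2, 8), (6.5, 8), (8, 1)], period=cycle),
        "theta2": keyframes([(0, 0), (0.5, 0), (2, -10), (6.5, -10), (8, 0)], period=cycle),
        "theta3": keyframes([(0, 10), (3.5, 10), (5, 35), (6.5, 35), (8, 10)], period=cycle),
        "theta4": keyframes([(0, 36), (0.5, 36), (2, 80), (6.5, 80), (8, 36)], period=cycle),
        "theta6": keyframes([(0, 5), (2, 5), (3.5, 85), (6.5, 85), (8, 5)], period=cycle),
        "theta7": keyframes([(0, 0), (5, 0), (5.75, -45), (6.5, 0), (8, 0)], period=cycle),
    }
    return MotionSpec(
        duration_s=2 * cycle,
        angles=angles,
        category="frontal_YZ",
        beta_deg=0.0,
        gamma_deg=90.0,
        alpha_deg=30.0,
        p_lorg=(100.0, 1400.0, -200.0),
        noise_sd=noise_sd,
        seed=seed,
        name="fig_sequence",
    )


def wiggle_presets(noise_sd: float = 0.0, seed: int = 0) -> dict[str, MotionSpec]:
    """Four wiggling-motion classes for the motion-description experiments.

    Classes 1 and 2 wiggle in front of and beside the trunk; classes 3 and 4
    share a fixed humerus-forearm relative posture (elbow held at 90 deg) and
    differ only in the humerus rotation about the vertical axis, making them
    similar but distinct.
    """
    base = dict(
        duration_s=10.0,
        category="frontal_YZ",
        beta_deg=0.0,
        gamma_deg=90.0,
        alpha_deg=30.0,
        p_lorg=(100.0, 1400.0, -200.0),
        noise_sd=noise_sd,
    )
    return {
        "wiggle1": MotionSpec(
            angles={
                "theta1": sine(3, 2, 0.5),
                "theta3": sine(10, 4, 0.5),
                "theta4": sine(40, 8, 0.5),
                "theta6": sine(25, 10, 0.5, phase_deg=90),
                "theta7": sine(5, 4, 0.5),
            },
            seed=seed,
            name="wiggle1",
            **base,
        ),
        "wiggle2": MotionSpec(
            angles={
                "theta2": sine(-4, 3, 0.4),
                "theta3": sine(75, 8, 0.4),
                "theta4": sine(55, 10, 0.4),
                "theta6": sine(15, 8, 0.8),
            },
            seed=seed + 1,
            name="wiggle2",
            **base,
        ),
        "wiggle3": MotionSpec(
            angles={
                "theta3": sine(20, 8, 0.5),
                "theta4": constant(60.0),
                "theta6": constant(90.0),
            },
            seed=seed + 2,
            name="wiggle3",
            **base,
        ),
        "wiggle4": MotionSpec(
            angles={
                "theta3": sine(55, 8, 0.7),
                "theta4": constant(60.0),
                "theta6": constant(90.0),
            },
            seed=seed + 3,
            name="wiggle4",
            **base,
        ),
    }


def rest_preset(duration_s: float = 2.0, noise_sd: float = 0.0, seed: int = 0) -> MotionSpec:
    """All angles at rest; useful for calibration and smoke tests."""
    return MotionSpec(
        duration_s=duration_s,
        angles={},
        beta_deg=0.0,
        gamma_deg=90.0,
        alpha_deg=30.0,
        p_lorg=(100.0, 1400.0, -200.0),
        noise_sd=noise_sd,
        seed=seed,
        name="rest",
    )


PRESETS = {
    "fig_sequence": fig_sequence_preset,
    "rest": rest_preset,
}


def preset(name: str, noise_sd: float = 0.0, seed: int = 0) -> MotionSpec:
    """Look up a preset by name (``fig_sequence``, ``rest``, ``wiggle1``..``wiggle4``)."""
    if name in PRESETS:
        return PRESETS[name](noise_sd=noise_sd, seed=seed)
    if name.startswith("wiggle"):
        presets = wiggle_presets(noise_sd=noise_sd, seed=seed)
        if name in presets:
            return presets[name]
    raise ConfigError(
        f"unknown preset {name!r}; available: fig_sequence, rest, wiggle1..wiggle4"
    )
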