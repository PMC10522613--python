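"""Simplified upper-limb model: segments, marker bookkeeping, triangle selection.

The limb is modeled as four rigid body segments (clavicle, humerus, forearm,
third metacarpal) with eight rotational degrees of freedom: two at the
sternoclavicular joint (θ1 about X, θ2 about Y), three at the glenohumeral
joint (θ3 about Y, θ4 about Z, θ5 about X), one at the elbow (θ6) and two at
the wrist (θ7 about X, θ8 about Z).  Each DOF is characterized by one spatial
triangle built from measured markers (points 3, 4, 8, 9, 10, 13) and
constructed reference points (1, 2, 5, 6, 7, 11, 12).

Units are millimetres for all coordinates and lengths, degrees for angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import ConfigError, FrameTagError, InvalidModelError

#: ids of the measured (marker) points
ACTUAL_POINT_IDS = frozenset({3, 4, 8, 9, 10, 13})
#: ids of points fixed in the local frame (clavicle reference points)
FIXED_POINT_IDS = frozenset({1, 2})
#: ids of points constructed from the measured ones
VIRTUAL_POINT_IDS = frozenset({5, 6, 7, 11, 12})

ANGLE_LABELS = tuple(f"theta{i}" for i in range(1, 9))

#: marker column names in file order (sternoclavicular, acromioclavicular,
#: glenohumeral, elbow, wrist, third-metacarpal end)
MARKER_NAMES = ("M3", "M4", "M8", "M9", "M10", "M13")


@dataclass(frozen=True)
class Point3:
    """A 3D point in millimetres, tagged with the frame it is expressed in."""

    x: float
    y: float
    z: float
    frame_tag: str = "world"

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("Point3 coordinates must be finite")
        if self.frame_tag not in ("world", "local"):
            raise ValueError(f"unknown frame tag {self.frame_tag!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a, frame_tag: str = "world") -> "Point3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame_tag)

    def _check_frame(self, other: "Point3") -> None:
        if self.frame_tag != other.frame_tag:
            raise FrameTagError(
                f"mixing frames {self.frame_tag!r} and {other.frame_tag!r}"
            )

    def __sub__(self, other: "Point3") -> np.ndarray:
        self._check_frame(other)
        return self.xyz - other.xyz

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self - other))


@dataclass(frozen=True)
class TriangleSpec:
    """One row entry of the segment table: a triangle, its axis and its angle.

    ``vertex_ids`` are stored in matrix row order: the reference (virtual or
    head) vertex first, then the two shared segment vertices.  This ordering
    fixes the sign of the projected areas used by the inverse solver.
    """

    segment_id: int
    vertex_ids: tuple[int, int, int]
    axis: str  # one of X, Y, Z, EL
    angle_label: str  # theta1 .. theta8

    def __post_init__(self):
        if self.axis not in ("X", "Y", "Z", "EL"):
            raise ValueError(f"bad axis {self.axis!r}")
        if self.angle_label not in ANGLE_LABELS:
            raise ValueError(f"bad angle label {self.angle_label!r}")

    @property
    def angle_index(self) -> int:
        return int(self.angle_label.removeprefix("theta"))


@dataclass(frozen=True)
class SegmentSpec:
    """Per-segment bookkeeping: DOFs, point ids and defining triangles."""

    segment_id: int
    name: str
    dof: str
    actual_ids: tuple[int, ...]
    virtual_ids: tuple[int, ...]
    triangles: tuple[TriangleSpec, ...]


def _build_segment_table() -> tuple[SegmentSpec, ...]:
    t = TriangleSpec
    return (
        SegmentSpec(
            1, "clavicle", "2-X/Y", (3, 4), (1, 2),
            (t(1, (1, 3, 4), "X", "theta1"), t(1, (2, 3, 4), "Y", "theta2")),
        ),
        SegmentSpec(
            2, "humerus", "3-X/Y/Z", (8, 9), (5, 6, 7),
            (
                t(2, (5, 8, 9), "Y", "theta3"),
                t(2, (6, 8, 9), "Z", "theta4"),
                t(2, (7, 8, 9), "X", "theta5"),
            ),
        ),
        SegmentSpec(
            3, "forearm", "1-EL", (8, 9, 10), (),
            (t(3, (8, 9, 10), "EL", "theta6"),),
        ),
        SegmentSpec(
            4, "metacarpal", "2-X/Z", (10, 13), (11, 12),
            (t(4, (11, 10, 13), "X", "theta7"), t(4, (12, 10, 13), "Z", "theta8")),
        ),
    )


_SEGMENT_TABLE = _build_segment_table()


@dataclass(frozen=True)
class LimbModel:
    """Segment lengths and constants of the simplified upper limb.

    L1..L4 are the clavicle, humerus, forearm and third-metacarpal lengths in
    millimetres.  ``clavicle_offset_deg`` is the angle between the clavicle
    and the frontal (Y-Z) plane in the natural downward rest pose.
    ``side`` selects the modeled arm; for ``"left"`` input coordinates are
    mirrored (x negated) before processing.
    """

    L1: float
    L2: float
    L3: float
    L4: float
    clavicle_offset_deg: float = 20.0
    side: str = "right"
    segment_table: tuple[SegmentSpec, ...] = field(default=_SEGMENT_TABLE, repr=False)

    def __post_init__(self):
        for name in ("L1", "L2", "L3", "L4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidModelError(f"segment length {name}={v!r} must be positive")
        if self.side not in ("right", "left"):
            raise InvalidModelError(f"side must be 'right' or 'left', got {self.side!r}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.L1, self.L2, self.L3, self.L4], dtype=float)

    @property
    def actual_point_ids(self) -> frozenset[int]:
        return ACTUAL_POINT_IDS

    def segment(self, segment_id: int) -> SegmentSpec:
        if not 1 <= segment_id <= 4:
            raise InvalidModelError(f"segment_id must be 1..4, got {segment_id}")
        return self.segment_table[segment_id - 1]

    def length_of(self, segment_id: int) -> float:
        return float(self.lengths[segment_id - 1])


def default_model(
    lengths: Iterable[float] = (150.0, 300.0, 260.0, 90.0),
    clavicle_offset_deg: float = 20.0,
    side: str = "right",
) -> LimbModel:
    """Build a :class:`LimbModel` from four segment lengths (mm).

    The default lengths are plausible adult values used throughout the test
    fixtures; real use should supply subject-specific lengths or calibrate
    them from a recording (see :func:`tribs.io.calibrate_lengths`).
    """
    L = tuple(float(v) for v in lengths)
    if len(L) != 4:
        raise InvalidModelError(f"expected four lengths, got {len(L)}")
    return LimbModel(*L, clavicle_offset_deg=clavicle_offset_deg, side=side)


def normalize_angle_label(label) -> str:
    """Accept ``3``, ``"3"``, ``"theta3"`` and return ``"theta3"``."""
    if isinstance(label, (int, np.integer)):
        label = f"theta{int(label)}"
    label = str(label)
    if label.isdigit():
        label = f"theta{label}"
    if label not in ANGLE_LABELS:
        raise ConfigError(f"unknown angle label {label!r}; expected theta1..theta8")
    return label


def select_triangles(model: LimbModel, wanted_angles) -> list[TriangleSpec]:
    """Return one :class:`TriangleSpec` per requested angle, ordered by θ index.

    ``wanted_angles`` is any nonempty collection of angle labels
    (``"theta1"``..``"theta8"`` or the integers 1..8).
    """
    labels = {normalize_angle_label(a) for a in wanted_angles}
    if not labels:
        raise ConfigError("wanted_angles must be a nonempty subset of theta1..theta8")
    by_label = {
        tri.angle_label: tri
        for seg in model.segment_table
        for tri in seg.triangles
    }
    return [by_label[lab] for lab in sorted(labels, key=lambda s: int(s[5:]))]


def load_model_config(source) -> LimbModel:
    """Read a model config (YAML mapping or dict) into a :class:`LimbModel`.

    Expected keys: ``lengths_mm`` (mapping with L1..L4), optional
    ``clavicle_offset_deg`` and ``side``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    elif isinstance(source, Mapping):
        cfg = dict(source)
    else:
        raise ConfigError(f"cannot read model config from {type(source).__name__}")
    try:
        lengths = cfg["lengths_mm"]
        L = [float(lengths[k]) for k in ("L1", "L2", "L3", "L4")]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"model config missing lengths_mm.L1..L4: {exc}") from exc
    return default_model(
        L,
        clavicle_offset_deg=float(cfg.get("clavicle_offset_deg", 20.0)),
        side=cfg.get("side", "right"),
    )
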