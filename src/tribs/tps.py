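"""Triangular primitive space (TPS) machinery.

A spatial triangle is summarized by the three signed areas of its projections
onto the X-Y, X-Z and Y-Z planes; those three numbers are the coordinates of
one point in TPS (axes M, N, U).  The Euclidean triangle area equals the norm
of the TPS point, so degenerate (zero-area) triangles map to the TPS origin
and no configuration is singular.

Each body segment contributes k triangles (k = 2, 3, 1, 2 for the clavicle,
humerus, forearm and metacarpal).  Summing the per-triangle 3x3 projection
coordinate matrices and squaring gives the segment matrix E_h, whose third
column has a closed form in the vertex coordinate sums.  Stacking the four
third columns over the segment lengths yields the 4x4 Euclidean body-segment
matrix E_O; assembling the four TPS plane matrices into blocks yields the 6x6
TPS body-segment matrix E_T.  E_O and E_T are the per-frame motion
descriptors consumed by :mod:`tribs.descriptors`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .model import LimbModel, TriangleSpec
from .virtual_points import PointSet

#: TPS modeling case per segment id: the clavicle and metacarpal keep two
#: informative triangles (case 2: two points + origin), the humerus three
#: (case 1), the forearm one (case 3: point + its M-axis foot + origin).
SEGMENT_CASE = {1: 2, 2: 1, 3: 3, 4: 2}


@dataclass(frozen=True)
class SpatialTriangle:
    """An ordered spatial triangle (reference vertex first)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    segment_id: int = 0
    triangle_index: int = 0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
            if not np.all(np.isfinite(getattr(self, name))):
                raise GeometryError(f"triangle vertex {name} must be finite")


def triangle_from_spec(pts: PointSet, spec: TriangleSpec, index: int = 0) -> SpatialTriangle:
    """Instantiate the triangle of one segment-table row from a point set."""
    i, j, k = spec.vertex_ids
    return SpatialTriangle(pts[i], pts[j], pts[k], spec.segment_id, index)


@dataclass(frozen=True)
class ProjectedAreas:
    """Signed projected areas of one triangle and their coordinate matrices.

    ``st_m``, ``st_n``, ``st_u`` are the literal 3x3 matrices (coordinate
    pair columns plus a ones column); ``s_m``, ``s_n``, ``s_u`` are the
    signed half-determinants, evaluated in vertex-difference form for
    numerical stability (algebraically identical to ±det/2).
    """

    s_m: float
    s_n: float
    s_u: float
    st_m: np.ndarray
    st_n: np.ndarray
    st_u: np.ndarray


def projected_areas(tri: SpatialTriangle) -> ProjectedAreas:
    """Signed areas of the projections onto the X-Y, X-Z and Y-Z planes."""
    a, b, c = tri.a, tri.b, tri.c
    ones = np.ones(3)
    st_m = np.column_stack([(a[0], b[0], c[0]), (a[1], b[1], c[1]), ones])
    st_n = np.column_stack([(a[0], b[0], c[0]), (a[2], b[2], c[2]), ones])
    st_u = np.column_stack([(a[1], b[1], c[1]), (a[2], b[2], c[2]), ones])
    u = b - a
    v = c - a
    s_m = 0.5 * (u[0] * v[1] - u[1] * v[0])
    s_n = 0.5 * (u[0] * v[2] - u[2] * v[0])
    s_u = 0.5 * (u[1] * v[2] - u[2] * v[1])
    return ProjectedAreas(s_m, s_n, s_u, st_m, st_n, st_u)


def triangle_area(pa: ProjectedAreas) -> float:
    """Euclidean triangle area from the projected areas: √(s_m²+s_n²+s_u²)."""
    return float(np.sqrt(pa.s_m**2 + pa.s_n**2 + pa.s_u**2))


@dataclass(frozen=True)
class TPSPoint:
    """One spatial triangle seen as a point of TPS (signed coordinates).

    The defining statement fixes only the magnitudes |M| = |S_m| etc.; the
    signs are carried so that the inverse solver can recover direction from
    the humerus determinants.
    """

    m: float
    n: float
    u: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.n, self.u])

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array))


def tps_point(pa: ProjectedAreas) -> TPSPoint:
    return TPSPoint(pa.s_m, pa.s_n, pa.s_u)


def segment_matrix(
    areas: list[ProjectedAreas],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Segment matrix E_h, its third column and the segment area |S_BS-h|.

    E_h = (Σ ST_m)² + (Σ ST_n)² + (Σ ST_u)² over the segment's k triangles
    (matrix squares).  |S_BS-h| = ½√(Σ_j det[(Σ_i ST_(h,i),j)²]).  All
    triangles of one segment must be row-ordered consistently (reference
    vertex, shared vertex i, shared vertex j).
    """
    k = len(areas)
    if not 1 <= k <= 3:
        raise GeometryError(f"a segment has 1..3 triangles, got {k}")
    shared = [np.asarray(pa.st_m[1:, :2]) for pa in areas]
    for other in shared[1:]:
        if not np.allclose(shared[0], other, rtol=0, atol=1e-9):
            raise GeometryError(
                "inconsistent row ordering: segment triangles must share "
                "their second and third vertices"
            )
    sum_m = sum(pa.st_m for pa in areas)
    sum_n = sum(pa.st_n for pa in areas)
    sum_u = sum(pa.st_u for pa in areas)
    e_h = sum_m @ sum_m + sum_n @ sum_n + sum_u @ sum_u
    area = 0.5 * float(
        np.sqrt(
            np.linalg.det(sum_m) ** 2
            + np.linalg.det(sum_n) ** 2
            + np.linalg.det(sum_u) ** 2
        )
    )
    return e_h, e_h[:, 2].copy(), area


def segment_third_column_closed_form(
    head_points: list[np.ndarray], p_i: np.ndarray, p_j: np.ndarray, k: int
) -> np.ndarray:
    """Closed form of the third column of E_h.

    With ΣP_x = x + y + z the column is
    (2k·Σ_heads ΣP + 3k², 2k²·ΣP_i + 3k², 2k²·ΣP_j + 3k²).
    """
    s_heads = float(sum(np.sum(p) for p in head_points))
    return np.array(
        [
            2.0 * k * s_heads + 3.0 * k**2,
            2.0 * k**2 * float(np.sum(p_i)) + 3.0 * k**2,
            2.0 * k**2 * float(np.sum(p_j)) + 3.0 * k**2,
        ]
    )


def body_matrix_euclid(third_columns: list[np.ndarray], model: LimbModel) -> np.ndarray:
    """4x4 Euclidean body-segment matrix: columns E_h^P over the length row."""
    if len(third_columns) != 4:
        raise GeometryError("body_matrix_euclid needs all four segment columns")
    top = np.column_stack([np.asarray(c, dtype=float).reshape(3) for c in third_columns])
    return np.vstack([top, model.lengths])


def tps_plane(points: list[TPSPoint], case: int) -> np.ndarray:
    """3x3 TPS plane matrix of one segment for the given modeling case.

    The symbolic first row of the plane matrix is a query point (M, N, U);
    for the numeric descriptor it is evaluated at the TPS origin, making
    row 1 = −P_j.  Cases: 1 → three triangle points; 2 → two points with the
    origin appended; 3 → one point, its perpendicular foot on the M axis and
    the origin; 4 → no informative triangle, the zero matrix.
    """
    expected = {1: 3, 2: 2, 3: 1, 4: 0}
    if case not in expected:
        raise GeometryError(f"unknown TPS case {case}")
    if len(points) != expected[case]:
        raise GeometryError(
            f"TPS case {case} needs {expected[case]} point(s), got {len(points)}"
        )
    if case == 4:
        return np.zeros((3, 3))
    coords = [p.as_array for p in points]
    if case == 3:
        coords.append(np.array([coords[0][0], 0.0, 0.0]))  # foot on the M axis
    if case in (2, 3):
        coords.append(np.zeros(3))
    p_i, p_j, p_k = coords
    return np.vstack([-p_j, p_i - p_j, p_k - p_j])


def body_matrix_tps(planes: list[np.ndarray]) -> np.ndarray:
    """6x6 TPS body-segment matrix: block layout [[S¹, S²], [S³, S⁴]]."""
    if len(planes) != 4:
        raise GeometryError("body_matrix_tps needs all four segment planes")
    s1, s2, s3, s4 = (np.asarray(p, dtype=float) for p in planes)
    for s in (s1, s2, s3, s4):
        if s.shape != (3, 3):
            raise GeometryError("each TPS plane matrix must be 3x3")
    return np.block([[s1, s2], [s3, s4]])


@dataclass(frozen=True)
class BodySegmentMatrices:
    """Per-frame pose summary: segment matrices and the E_O / E_T descriptors."""

    e_h: tuple[np.ndarray, ...]  # four 3x3 segment matrices
    e_h_p: tuple[np.ndarray, ...]  # their third columns
    segment_areas: tuple[float, ...]  # |S_BS-h|
    tps_points: dict[int, list[TPSPoint]]  # segment id -> triangle TPS points
    e_o: np.ndarray  # 4x4
    s_tps: tuple[np.ndarray, ...]  # four 3x3 plane matrices
    e_t: np.ndarray  # 6x6


def build_matrices(pts: PointSet, model: LimbModel) -> BodySegmentMatrices:
    """Compute every TPS/Euclidean matrix quantity for one pose."""
    e_hs, cols, seg_areas, planes = [], [], [], []
    tps_pts: dict[int, list[TPSPoint]] = {}
    for seg in model.segment_table:
        areas = [
            projected_areas(triangle_from_spec(pts, tri, idx))
            for idx, tri in enumerate(seg.triangles)
        ]
        e_h, col, area = segment_matrix(areas)
        e_hs.append(e_h)
        cols.append(col)
        seg_areas.append(area)
        seg_points = [tps_point(pa) for pa in areas]
        tps_pts[seg.segment_id] = seg_points
        planes.append(tps_plane(seg_points, SEGMENT_CASE[seg.segment_id]))
    return BodySegmentMatrices(
        e_h=tuple(e_hs),
        e_h_p=tuple(cols),
        segment_areas=tuple(seg_areas),
        tps_points=tps_pts,
        e_o=body_matrix_euclid(cols, model),
        s_tps=tuple(planes),
        e_t=body_matrix_tps(planes),
    )
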