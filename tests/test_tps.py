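"""Projected areas, segment matrices and the TPS body-segment machinery."""

import numpy as np
import pytest

from tribs import (
    body_matrix_euclid,
    body_matrix_tps,
    build_matrices,
    build_point_set,
    projected_areas,
    segment_matrix,
    tps_plane,
    triangle_area,
)
from tribs.errors import GeometryError
from tribs.tps import (
    SpatialTriangle,
    TPSPoint,
    segment_third_column_closed_form,
    tps_point,
    triangle_from_spec,
)


def tri(a, b, c):
    return SpatialTriangle(np.asarray(a, float), np.asarray(b, float), np.asarray(c, float))


class TestProjectedAreas:
    def test_unit_right_triangle(self):
        pa = projected_areas(tri([0, 0, 0], [1, 0, 0], [0, 1, 0]))
        assert (pa.s_m, pa.s_n, pa.s_u) == pytest.approx((0.5, 0.0, 0.0))

    def test_vertex_swap_negates_all_signs(self, rng):
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3)) * 100
            pa = projected_areas(tri(a, b, c))
            sw = projected_areas(tri(a, c, b))
            assert (sw.s_m, sw.s_n, sw.s_u) == pytest.approx(
                (-pa.s_m, -pa.s_n, -pa.s_u)
            )

    def test_collinear_vertices_zero(self):
        pa = projected_areas(tri([0, 0, 0], [1, 1, 1], [2, 2, 2]))
        assert (pa.s_m, pa.s_n, pa.s_u) == (0.0, 0.0, 0.0)

    def test_signed_areas_are_half_matrix_determinants(self, rng):
        for _ in range(100):
            a, b, c = rng.normal(size=(3, 3)) * 300
            pa = projected_areas(tri(a, b, c))
            for s, st in ((pa.s_m, pa.st_m), (pa.s_n, pa.st_n), (pa.s_u, pa.st_u)):
                det = 0.5 * np.linalg.det(st)
                assert s == pytest.approx(det, abs=1e-6 * max(1.0, abs(s)))


class TestTriangleArea:
    def test_unit_right_triangle(self):
        assert triangle_area(projected_areas(tri([0, 0, 0], [1, 0, 0], [0, 1, 0]))) == 0.5

    def test_matches_cross_product_oracle(self, rng):
        for _ in range(1000):
            a, b, c = rng.normal(size=(3, 3)) * 400
            area = triangle_area(projected_areas(tri(a, b, c)))
            oracle = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            assert area == pytest.approx(oracle, rel=1e-12, abs=1e-12)

    def test_degenerate_is_zero(self):
        assert triangle_area(projected_areas(tri([1, 2, 3], [1, 2, 3], [4, 5, 6]))) == 0.0

    def test_rigid_motion_invariance(self, rng):
        from tribs.frames import build_rotation

        a, b, c = rng.normal(size=(3, 3)) * 200
        base = triangle_area(projected_areas(tri(a, b, c)))
        r = build_rotation(33.0, -50.0, 140.0)
        shift = rng.normal(size=3) * 1000
        moved = triangle_area(projected_areas(tri(r @ a + shift, r @ b + shift, r @ c + shift)))
        assert moved == pytest.approx(base, rel=1e-10)


class TestSegmentMatrix:
    def test_all_zero_single_triangle_third_column(self):
        pa = projected_areas(tri([0, 0, 0], [0, 0, 0], [0, 0, 0]))
        _, col, _ = segment_matrix([pa])
        assert np.allclose(col, [3.0, 3.0, 3.0])

    def test_closed_form_matches_brute_force(self, model, random_local_poses):
        """The closed form of E_h's third column equals the matrix square."""
        for _, local in random_local_poses(100):
            pts = build_point_set(local, model)
            for seg in model.segment_table:
                pas = [projected_areas(triangle_from_spec(pts, t)) for t in seg.triangles]
                _, col, _ = segment_matrix(pas)
                heads = [pts[t.vertex_ids[0]] for t in seg.triangles]
                p_i = pts[seg.triangles[0].vertex_ids[1]]
                p_j = pts[seg.triangles[0].vertex_ids[2]]
                expected = segment_third_column_closed_form(heads, p_i, p_j, len(pas))
                assert np.allclose(col, expected, rtol=1e-6)

    def test_forearm_segment_area_is_triangle_area(self, model, random_local_poses):
        (_, local), = random_local_poses(1)
        pts = build_point_set(local, model)
        (spec,) = model.segment(3).triangles
        pa = projected_areas(triangle_from_spec(pts, spec))
        _, _, seg_area = segment_matrix([pa])
        assert seg_area == pytest.approx(triangle_area(pa), rel=1e-12)

    def test_triangle_count_bounds(self):
        pa = projected_areas(tri([0, 0, 0], [1, 0, 0], [0, 1, 0]))
        with pytest.raises(GeometryError):
            segment_matrix([])
        with pytest.raises(GeometryError):
            segment_matrix([pa] * 4)

    def test_inconsistent_row_ordering_rejected(self):
        pa1 = projected_areas(tri([0, 0, 1], [1, 0, 0], [0, 1, 0]))
        pa2 = projected_areas(tri([0, 0, 1], [2, 0, 0], [0, 2, 0]))  # different shared vertices
        with pytest.raises(GeometryError, match="row ordering"):
            segment_matrix([pa1, pa2])


class TestBodyMatrices:
    def test_euclid_bottom_row_is_lengths(self, model, random_local_poses):
        (_, local), = random_local_poses(1)
        mats = build_matrices(build_point_set(local, model), model)
        assert np.array_equal(mats.e_o[3], model.lengths)
        assert mats.e_o.shape == (4, 4) and mats.e_t.shape == (6, 6)

    def test_euclid_missing_segment_rejected(self, model):
        with pytest.raises(GeometryError):
            body_matrix_euclid([np.zeros(3)] * 3, model)

    def test_euclid_continuity_under_perturbation(self, model, random_local_poses):
        (_, local), = random_local_poses(1)
        base = build_matrices(build_point_set(local, model), model).e_o
        prev = np.inf
        for eps in (1.0, 1e-2, 1e-4):
            bumped = {k: v + eps * np.array([1.0, -0.5, 0.25]) for k, v in local.items()}
            diff = np.linalg.norm(
                build_matrices(build_point_set(bumped, model), model).e_o - base
            )
            assert diff < prev
            prev = diff
        assert prev < 1e-2 * np.linalg.norm(base)

    def test_tps_block_placement(self, model, random_local_poses):
        (_, local), = random_local_poses(1)
        mats = build_matrices(build_point_set(local, model), model)
        s1, s2, s3, s4 = mats.s_tps
        assert mats.e_t[0, 3] == s2[0, 0]
        assert np.array_equal(mats.e_t[:3, :3], s1)
        assert np.array_equal(mats.e_t[3:, 3:], s4)

    def test_tps_missing_plane_rejected(self):
        with pytest.raises(GeometryError):
            body_matrix_tps([np.zeros((3, 3))] * 3)


class TestTPSPoints:
    def test_unit_right_triangle_point(self):
        p = tps_point(projected_areas(tri([0, 0, 0], [1, 0, 0], [0, 1, 0])))
        assert (p.m, p.n, p.u) == pytest.approx((0.5, 0.0, 0.0))

    def test_norm_equals_area(self, rng):
        for _ in range(1000):
            a, b, c = rng.normal(size=(3, 3)) * 250
            pa = projected_areas(tri(a, b, c))
            assert tps_point(pa).norm == pytest.approx(triangle_area(pa), rel=1e-12)

    def test_degenerate_maps_to_origin(self):
        p = tps_point(projected_areas(tri([1, 1, 1], [2, 2, 2], [3, 3, 3])))
        assert (p.m, p.n, p.u) == (0.0, 0.0, 0.0)


class TestTPSPlane:
    def test_case4_zero_matrix(self):
        assert np.array_equal(tps_plane([], 4), np.zeros((3, 3)))

    def test_case2_row_structure(self):
        p = TPSPoint(1.0, 2.0, 3.0)
        q = TPSPoint(-1.0, 0.5, 2.0)
        s = tps_plane([p, q], 2)
        assert np.allclose(s[0], -q.as_array)
        assert np.allclose(s[1], p.as_array - q.as_array)
        assert np.allclose(s[2], -q.as_array)

    def test_case3_m_axis_foot(self):
        p = TPSPoint(2.0, 3.0, 4.0)
        s = tps_plane([p], 3)
        aux = np.array([2.0, 0.0, 0.0])
        assert np.allclose(s[0], -aux)
        assert np.allclose(s[1], p.as_array - aux)
        assert np.allclose(s[2], -aux)

    def test_point_count_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            tps_plane([TPSPoint(1, 2, 3)], 2)
        with pytest.raises(GeometryError):
            tps_plane([], 5)
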