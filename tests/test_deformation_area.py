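"""Signed deviation analysis, deformation region, boundary statistics."""

import numpy as np
import pytest

from prosthoface.deformation_area import (
    ala_tragus_plane,
    boundary_stats,
    cohort_boundary_summary,
    deformation_region,
    region_boundary,
    signed_deviation,
)
from prosthoface.errors import LandmarkSchemaError, MeshValidationError
from prosthoface.mesh_io import LandmarkSet
from prosthoface.registration import RegionMask, RigidTransform
from prosthoface.synthetic import plane_grid
from scipy.spatial.transform import Rotation


class TestSignedDeviation:
    def test_identical_meshes_all_zero(self, default_face):
        mesh, _ = default_face
        rep = signed_deviation(mesh, mesh)
        np.testing.assert_allclose(rep.signed_distance, 0.0, atol=1e-9)
        assert not rep.mask.any()

    @pytest.mark.parametrize("offset,expect_masked", [(0.19, False), (0.21, True), (0.5, True)])
    def test_plane_offset_exact_and_bracketing(self, flat_grid, offset, expect_masked):
        test = flat_grid.with_vertices(flat_grid.vertices + [0, 0, offset])
        rep = signed_deviation(flat_grid, test, critical=0.2)
        np.testing.assert_allclose(rep.signed_distance, offset, atol=1e-12)
        assert rep.mask.all() == expect_masked
        assert rep.mask.any() == expect_masked

    def test_sign_follows_reference_normal(self, flat_grid):
        below = flat_grid.with_vertices(flat_grid.vertices - [0, 0, 0.3])
        rep = signed_deviation(flat_grid, below)
        np.testing.assert_allclose(rep.signed_distance, -0.3, atol=1e-12)

    def test_rigid_motion_invariance(self, default_pair):
        pre, post = default_pair.pre_mesh, default_pair.post_mesh
        rep0 = signed_deviation(pre, post)
        g = RigidTransform(
            Rotation.from_rotvec([0.3, -0.1, 0.2]).as_matrix(), np.array([4.0, 5.0, -6.0])
        )
        rep1 = signed_deviation(g.apply_mesh(pre), g.apply_mesh(post))
        np.testing.assert_allclose(
            rep1.signed_distance, rep0.signed_distance, atol=1e-6
        )

    def test_empty_mesh_rejected(self, flat_grid):
        import prosthoface.mesh_io as mio

        empty = mio.TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshValidationError):
            signed_deviation(flat_grid, empty)


class TestDeformationRegion:
    def test_recovers_synthetic_support(self, default_pair):
        rep = signed_deviation(default_pair.pre_mesh, default_pair.post_mesh)
        region = deformation_region(rep, default_pair.post_mesh)
        truly = (
            np.abs(
                default_pair.post_mesh.vertices[:, 2]
                - default_pair.pre_mesh.vertices[:, 2]
            )
            > rep.critical
        )
        assert np.all(~region.mask | default_pair.support.mask)  # region within support
        recovered = (region.mask & truly).sum() / truly.sum()
        assert recovered >= 0.95

    def test_keeps_largest_component_only(self, flat_grid):
        rep = signed_deviation(flat_grid, flat_grid)
        # forge two disjoint super-threshold blobs: rows 0-1 (40 verts) and
        # the last row (20 verts)
        d = rep.signed_distance.copy()
        d[:40] = 0.5
        d[-20:] = 0.5
        rep = type(rep)(d, 0.2)
        region = deformation_region(rep, flat_grid)
        assert region.count == 40
        assert region.mask[:40].all()

    def test_empty_mask_flagged_not_error(self, flat_grid):
        rep = signed_deviation(flat_grid, flat_grid)
        region = deformation_region(rep, flat_grid)
        assert region.count == 0
        assert region.empty_flagged

    def test_boundary_vertices_touch_outside(self, default_pair):
        rep = signed_deviation(default_pair.pre_mesh, default_pair.post_mesh)
        region = deformation_region(rep, default_pair.post_mesh)
        b = region_boundary(default_pair.post_mesh, region)
        assert b.size > 0
        inside = region.mask
        adj = default_pair.post_mesh.adjacency
        for i in b[:20]:
            nb = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
            assert inside[i] and (~inside[nb]).any()


class TestAlaTragusPlane:
    @staticmethod
    def _landmarks(points):
        base = {
            "left_tragus": points[0],
            "right_tragus": points[1],
            "left_ala": points[2],
            "right_ala": points[3],
            "nasal_tip": [0.0, 0.0, 50.0],
        }
        return LandmarkSet(base)

    def test_coplanar_points_zero_residual(self):
        pts = [[70.0, 0, 0], [-70, 0, 0], [10, -8, 35], [-10, -8, 35]]
        plane = ala_tragus_plane(self._landmarks(pts))
        d = plane.signed_distance(np.asarray(pts, dtype=float))
        np.testing.assert_allclose(d, 0.0, atol=1e-9)
        assert plane.normal[1] > 0

    def test_tls_bound_under_perturbation(self):
        eps = 0.05
        pts = np.array([[70.0, 0, 0], [-70, 0, 0], [10, -8, 35], [-10, -8, 35]])
        pts[:, 2] += np.array([eps, -eps, eps, -eps])
        plane = ala_tragus_plane(self._landmarks(pts.tolist()))
        assert np.max(np.abs(plane.signed_distance(pts))) <= eps + 1e-9

    def test_missing_ala_is_landmark_error(self):
        lm = LandmarkSet(
            {
                "left_tragus": [70.0, 0, 0],
                "right_tragus": [-70, 0, 0],
                "nasal_tip": [0, 0, 50],
            }
        )
        with pytest.raises(LandmarkSchemaError):
            ala_tragus_plane(lm)


class TestBoundaryStats:
    def test_hand_computed_distances(self, default_pair):
        """Boundary stats must equal direct recomputation from the boundary
        vertex set (independent formulas)."""
        mesh = default_pair.post_mesh
        lm = default_pair.post_landmarks
        rep = signed_deviation(default_pair.pre_mesh, mesh)
        region = deformation_region(rep, mesh)
        stats = boundary_stats(region, mesh, lm)
        b = mesh.vertices[region_boundary(mesh, region)]
        plane = ala_tragus_plane(lm)
        assert np.isclose(stats.upper_distance, abs(plane.signed_distance(b).max()), atol=1e-9)
        assert np.isclose(
            stats.lower_distance,
            np.sqrt(((b - lm["menton"]) ** 2).sum(axis=1)).min(),
            atol=1e-9,
        )
        lat = b[np.argmax(b[:, 0])]
        expected = np.linalg.norm(lat - lm["left_commissure"]) / np.linalg.norm(
            lm["left_tragus"] - lm["left_commissure"]
        )
        assert np.isclose(stats.left_ratio, expected, atol=1e-9)

    def test_region_touching_menton_gives_zero_lower_distance(self, default_pair):
        mesh = default_pair.post_mesh
        lm = default_pair.post_landmarks
        menton_idx = lm.vertex_indices["menton"]
        mask = np.zeros(mesh.vertex_count, bool)
        # a tiny region whose boundary includes the menton vertex itself
        mask[menton_idx] = True
        mask[mesh.neighbors(menton_idx)[:2]] = True
        stats = boundary_stats(RegionMask(mask), mesh, lm)
        assert stats.lower_distance == 0.0

    def test_invariance_under_joint_rigid_motion(self, default_pair):
        mesh = default_pair.post_mesh
        lm = default_pair.post_landmarks
        rep = signed_deviation(default_pair.pre_mesh, mesh)
        region = deformation_region(rep, mesh)
        s0 = boundary_stats(region, mesh, lm)
        g = RigidTransform(
            Rotation.from_rotvec([-0.2, 0.4, 0.1]).as_matrix(), np.array([1.0, 2.0, 3.0])
        )
        s1 = boundary_stats(region, g.apply_mesh(mesh), g.apply_landmarks(lm))
        for key in ("upper_distance", "lower_distance", "left_ratio", "right_ratio"):
            assert np.isclose(getattr(s0, key), getattr(s1, key), atol=1e-9)


class TestCohortSummary:
    def test_two_point_closed_form(self):
        from prosthoface.deformation_area import BoundaryStats

        a = BoundaryStats(1.0, 0.5, 0.8, 0.79)
        b = BoundaryStats(3.0, 0.5, 0.8, 0.79)
        table = cohort_boundary_summary([a, b])
        assert table.loc["upper_distance", "mean"] == 2.0
        assert np.isclose(table.loc["upper_distance", "sd"], np.sqrt(2.0))
        assert table.loc["lower_distance", "sd"] == 0.0

    def test_matches_one_pass_recomputation(self, rng):
        from prosthoface.deformation_area import BoundaryStats

        vals = rng.uniform(0.1, 3.0, size=(10, 4))
        stats = [BoundaryStats(*row) for row in vals]
        table = cohort_boundary_summary(stats)
        n = len(vals)
        mean = vals.sum(axis=0) / n
        sd = np.sqrt((np.sum(vals**2, axis=0) - n * mean**2) / (n - 1))
        np.testing.assert_allclose(table["mean"].to_numpy(), mean, atol=1e-9)
        np.testing.assert_allclose(table["sd"].to_numpy(), sd, atol=1e-9)

    def test_single_entry_rejected(self):
        from prosthoface.deformation_area import BoundaryStats

        with pytest.raises(ValueError):
            cohort_boundary_summary([BoundaryStats(1, 1, 1, 1)])
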