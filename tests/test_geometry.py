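"""Curvature estimation, isolines, feature detection, template assembly."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from prosthoface.errors import DetectionError, IsolineError, TemplateError
from prosthoface.geometry import (
    MIDLINE_ROLES,
    MIRROR_PAIRS,
    Isoline,
    build_feature_template,
    detect_feature_points,
    extract_isoline,
    mean_curvature,
    profile_curvature,
    vertex_normals,
)
from prosthoface.mesh_io import TriangleMesh
from prosthoface.registration import RigidTransform
from prosthoface.synthetic import cylinder_grid, icosphere, plane_grid


class TestVertexNormals:
    def test_flat_grid_normals_are_plus_z(self, flat_grid):
        n = vertex_normals(flat_grid)
        np.testing.assert_allclose(n, np.tile([0, 0, 1.0], (flat_grid.vertex_count, 1)))

    def test_sphere_normals_radial_within_2_degrees(self, unit_sphere):
        n = vertex_normals(unit_sphere)
        radial = unit_sphere.vertices / np.linalg.norm(
            unit_sphere.vertices, axis=1, keepdims=True
        )
        angles = np.degrees(np.arccos(np.clip(np.sum(n * radial, axis=1), -1, 1)))
        assert angles.max() < 2.0

    def test_single_triangle_normals_equal_face_normal(self):
        mesh = TriangleMesh(
            np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0]]), np.array([[0, 1, 2]])
        )
        n = vertex_normals(mesh)
        np.testing.assert_allclose(n, np.tile([0, 0, 1.0], (3, 1)))

    def test_unit_length(self, default_face):
        mesh, _ = default_face
        n = vertex_normals(mesh)
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)


class TestMeanCurvature:
    def test_plane_is_exactly_flat(self, flat_grid):
        h = mean_curvature(flat_grid).mean
        np.testing.assert_allclose(h, 0.0, atol=1e-9)

    @pytest.mark.parametrize("radius", [1.0, 10.0, 50.0])
    def test_sphere_closed_form(self, radius):
        mesh = icosphere(radius, 4)
        assert mesh.vertex_count >= 2500
        h = mean_curvature(mesh).mean
        # outward normals make the sphere's H negative
        assert np.all(h < 0)
        assert np.max(np.abs(np.abs(h) - 1.0 / radius)) < 0.05 / radius

    def test_cylinder_closed_form(self):
        radius = 2.0
        mesh = cylinder_grid(radius, 20.0)
        h = mean_curvature(mesh).mean
        away_from_caps = np.abs(mesh.vertices[:, 2]) < 6.0
        expected = 1.0 / (2 * radius)
        assert np.max(np.abs(np.abs(h[away_from_caps]) - expected)) < 0.1 * expected

    def test_field_mean_equals_edge_sample_mean(self, default_face):
        mesh, _ = default_face
        field = mean_curvature(mesh)
        recomputed = np.zeros(mesh.vertex_count)
        np.add.at(recomputed, field.edge_src, field.edge_k)
        recomputed /= field.neighborhood_size
        np.testing.assert_allclose(field.mean, recomputed, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        mesh = icosphere(5.0, 2)
        h0 = mean_curvature(mesh).mean
        r = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        g = RigidTransform(r, np.array([3.0, -7.0, 11.0]))
        h1 = mean_curvature(g.apply_mesh(mesh)).mean
        np.testing.assert_allclose(h0, h1, atol=1e-9)

    def test_scaling_law(self):
        """Scaling the surface by s scales H by 1/s."""
        base = icosphere(1.0, 3)
        h1 = mean_curvature(base).mean
        s = 7.0
        hs = mean_curvature(base.with_vertices(base.vertices * s)).mean
        np.testing.assert_allclose(hs, h1 / s, atol=1e-9)


def _height_field(fn, nx=60, ny=60, size=10.0):
    xs = np.linspace(-size / 2, size / 2, nx)
    ys = np.linspace(-size / 2, size / 2, ny)
    gx, gy = np.meshgrid(xs, ys)
    v = np.column_stack([gx.ravel(), gy.ravel(), fn(gx, gy).ravel()])
    faces = []
    for r in range(ny - 1):
        for c in range(nx - 1):
            v00, v01 = r * nx + c, r * nx + c + 1
            v10, v11 = (r + 1) * nx + c, (r + 1) * nx + c + 1
            faces += [[v00, v01, v11], [v00, v11, v10]]
    return TriangleMesh(v, np.asarray(faces))


class TestExtractIsoline:
    def test_height_field_section_matches_analytic(self):
        fn = lambda x, y: 0.3 * x**2 + 0.1 * y
        mesh = _height_field(fn)
        iso = extract_isoline(mesh, "x", 1.234)
        assert np.max(np.abs(iso.points[:, 0] - 1.234)) < 1e-9
        z_expected = fn(iso.points[:, 0], iso.points[:, 1])
        # linear interpolation across curved triangles: small O(h^2) sag
        assert np.max(np.abs(iso.points[:, 2] - z_expected)) < 6e-3

    def test_value_outside_bounding_box_is_error(self, flat_grid):
        with pytest.raises(IsolineError):
            extract_isoline(flat_grid, "x", 1e6)

    def test_sphere_great_circle_length(self, unit_sphere):
        iso = extract_isoline(unit_sphere, "x", 0.0)
        assert iso.closed
        assert abs(iso.length - 2 * np.pi) < 0.01 * 2 * np.pi

    def test_points_on_iso_plane(self, default_face):
        mesh, _ = default_face
        iso = extract_isoline(mesh, "y", -17.0)
        assert np.max(np.abs(iso.points[:, 1] + 17.0)) < 1e-6
        assert np.all(np.linalg.norm(np.diff(iso.points, axis=0), axis=1) > 0)


class TestProfileCurvature:
    def test_straight_line_is_zero(self):
        pts = np.column_stack([np.zeros(30), np.linspace(0, 5, 30), np.linspace(0, 2, 30)])
        iso = Isoline(pts, axis=0, value=0.0)
        np.testing.assert_allclose(profile_curvature(iso), 0.0, atol=1e-12)

    def test_circle_closed_form(self):
        r = 3.0
        t = np.linspace(0, np.pi, 100)
        pts = np.column_stack([np.zeros_like(t), r * np.cos(t), r * np.sin(t)])
        iso = Isoline(pts, axis=0, value=0.0)
        kappa = profile_curvature(iso)
        np.testing.assert_allclose(np.abs(kappa[3:-3]), 1.0 / r, rtol=0.02)

    def test_sine_extrema_at_crests(self):
        t = np.linspace(0, 4 * np.pi, 400)
        pts = np.column_stack([np.zeros_like(t), t, np.sin(t)])
        iso = Isoline(pts, axis=0, value=0.0)
        kappa = profile_curvature(iso)
        _, idx = detect_feature_points(iso, kappa, 4)
        crest_t = np.array([np.pi / 2, 3 * np.pi / 2, 5 * np.pi / 2, 7 * np.pi / 2])
        found_t = np.sort(t[idx])
        step = t[1] - t[0]
        assert np.max(np.abs(found_t - crest_t)) <= 2 * step


class TestDetectFeaturePoints:
    def test_straight_line_has_no_extrema(self):
        pts = np.column_stack([np.zeros(30), np.linspace(0, 5, 30), np.zeros(30)])
        iso = Isoline(pts, axis=0, value=0.0)
        kappa = profile_curvature(iso)
        with pytest.raises(DetectionError) as err:
            detect_feature_points(iso, kappa, 1)
        assert err.value.found == 0

    def test_tie_breaks_toward_smaller_arclength(self):
        # two identical bumps; k=1 must pick the first one
        t = np.linspace(0, 1, 201)
        kappa = np.exp(-((t - 0.3) ** 2) / 1e-3) + np.exp(-((t - 0.7) ** 2) / 1e-3)
        pts = np.column_stack([np.zeros_like(t), t, np.zeros_like(t)])
        iso = Isoline(pts, axis=0, value=0.0)
        _, idx = detect_feature_points(iso, kappa, 1)
        assert abs(t[idx[0]] - 0.3) < 0.01

    def test_requesting_too_many_reports_found_count(self):
        t = np.linspace(0, 2 * np.pi, 200)
        pts = np.column_stack([np.zeros_like(t), t, np.sin(t)])
        iso = Isoline(pts, axis=0, value=0.0)
        kappa = profile_curvature(iso)
        with pytest.raises(DetectionError) as err:
            detect_feature_points(iso, kappa, 10)
        assert 0 < err.value.found < 10


class TestFeatureTemplate:
    def test_twenty_nine_points_with_expected_roles(self, default_face):
        mesh, _ = default_face
        tpl = build_feature_template(mesh)
        assert len(tpl) == 29
        assert tpl.roles[0] == "A"
        assert tpl.vertex_indices is not None
        assert np.unique(tpl.vertex_indices).size == 29

    def test_nasal_tip_attains_max_z(self, default_face):
        mesh, _ = default_face
        tpl = build_feature_template(mesh)
        assert np.isclose(tpl.point("A")[2], mesh.vertices[:, 2].max())

    def test_mirror_symmetry_on_symmetric_face(self, default_face):
        mesh, _ = default_face
        tpl = build_feature_template(mesh)
        for left, right in MIRROR_PAIRS:
            pl, pr = tpl.point(left), tpl.point(right)
            assert abs(pl[0] + pr[0]) < 0.1
            assert abs(pl[1] - pr[1]) < 0.1
            assert abs(pl[2] - pr[2]) < 0.1
        for role in MIDLINE_ROLES:
            assert abs(tpl.point(role)[0]) < 0.1

    def test_translation_equivariance(self, default_face):
        mesh, _ = default_face
        tpl = build_feature_template(mesh)
        shift = np.array([0.0, 10.0, 0.0])
        tpl2 = build_feature_template(mesh.with_vertices(mesh.vertices + shift))
        np.testing.assert_allclose(tpl2.points, tpl.points + shift, atol=1e-9)

    def test_rigid_equivariance_with_landmarks(self, default_face, rng):
        mesh, lm = default_face
        tpl = build_feature_template(mesh, lm)
        r = Rotation.from_rotvec([0.2, 0.5, -0.3]).as_matrix()
        g = RigidTransform(r, np.array([5.0, -3.0, 8.0]))
        tpl2 = build_feature_template(g.apply_mesh(mesh), g.apply_landmarks(lm))
        np.testing.assert_allclose(tpl2.points, g.apply(tpl.points), atol=1e-6)

    def test_midpoint_constructions_exact(self, default_face):
        mesh, _ = default_face
        tpl = build_feature_template(mesh)
        np.testing.assert_array_equal(
            tpl.point("2"), (tpl.point("1") + tpl.point("3")) / 2.0
        )
        np.testing.assert_array_equal(
            tpl.point("G"), (tpl.point("A") + tpl.point("E")) / 2.0
        )
        np.testing.assert_array_equal(
            tpl.point("H"), (tpl.point("A") + tpl.point("F")) / 2.0
        )

    def test_featureless_sphere_fails_template(self):
        with pytest.raises(TemplateError):
            build_feature_template(icosphere(1.0, 4))
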