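"""Geometry kernel: analytic solids, primitive fits, symmetry operations."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from limbmech.errors import DegenerateGeometryError, MeshNotClosedError
from limbmech.mesh_core import (TriMesh, convex_hull, fit_cylinder,
                                fit_sphere, mesh_centroid, mesh_inertia,
                                mesh_volume, mirror_x, uniform_scale)


class TestMeshVolume:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_matches_analytic_sphere(self, icosphere):
        assert mesh_volume(icosphere) == pytest.approx(4 * np.pi / 3, rel=5e-3)

    def test_open_mesh_rejected_with_boundary_count(self, unit_cube):
        open_mesh = TriMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(MeshNotClosedError, match="boundary edge"):
            mesh_volume(open_mesh)
        assert open_mesh.boundary_edge_count() == 3

    def test_inverted_orientation_autoflipped(self, unit_cube):
        flipped = TriMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        assert mesh_volume(flipped) == pytest.approx(1.0, abs=1e-12)

    def test_retessellation_invariance(self, unit_cube):
        fine = TriMesh.from_trimesh(unit_cube.to_trimesh().subdivide())
        assert mesh_volume(fine) == pytest.approx(mesh_volume(unit_cube),
                                                  rel=1e-9)


class TestMeshCentroid:
    def test_unit_cube_centre(self, unit_cube):
        np.testing.assert_allclose(mesh_centroid(unit_cube), [0.5] * 3,
                                   atol=1e-12)

    def test_translation_equivariance(self, unit_cube):
        moved = TriMesh(unit_cube.vertices + [1.0, 0, 0], unit_cube.faces)
        np.testing.assert_allclose(mesh_centroid(moved), [1.5, 0.5, 0.5],
                                   atol=1e-12)

    def test_disjoint_cubes_weighted_average(self, unit_cube):
        union = TriMesh(
            np.vstack([unit_cube.vertices, unit_cube.vertices + [10.0, 0, 0]]),
            np.vstack([unit_cube.faces,
                       unit_cube.faces + len(unit_cube.vertices)]))
        np.testing.assert_allclose(mesh_centroid(union), [5.5, 0.5, 0.5],
                                   atol=1e-12)


class TestMeshInertia:
    def test_cube_diagonal_m_over_6(self, unit_cube):
        mass, com, inertia = mesh_inertia(unit_cube, density=1000.0)
        assert mass == pytest.approx(1000.0, abs=1e-9)
        np.testing.assert_allclose(com, [0.5] * 3, atol=1e-12)
        np.testing.assert_allclose(inertia, np.eye(3) * mass / 6.0, atol=1e-6)

    def test_density_linearity(self, icosphere):
        m1, _, i1 = mesh_inertia(icosphere, density=500.0)
        m2, _, i2 = mesh_inertia(icosphere, density=1000.0)
        assert m2 == pytest.approx(2 * m1, rel=1e-12)
        np.testing.assert_allclose(i2, 2 * i1, rtol=1e-12)

    def test_solid_sphere_two_fifths_mr2(self, icosphere):
        mass, _, inertia = mesh_inertia(icosphere, density=1.0)
        expected = 2.0 * mass * 1.0 ** 2 / 5.0
        np.testing.assert_allclose(np.diag(inertia), expected, rtol=1e-2)

    def test_positive_definite(self, icosphere):
        _, _, inertia = mesh_inertia(icosphere, density=1.0)
        assert np.all(np.linalg.eigvalsh(inertia) > 0)

    def test_nonpositive_density_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            mesh_inertia(unit_cube, density=0.0)


class TestConvexHull:
    def test_cube_corners(self):
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
        hull = convex_hull(corners)
        assert mesh_volume(hull) == pytest.approx(1.0, abs=1e-12)

    def test_interior_points_ignored(self):
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
        rng = np.random.default_rng(0)
        pts = np.vstack([corners, rng.uniform(0.2, 0.8, (50, 3))])
        assert mesh_volume(convex_hull(pts)) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(100, 3))
        h1 = convex_hull(pts)
        h2 = convex_hull(h1.vertices)
        assert mesh_volume(h2) == pytest.approx(mesh_volume(h1), rel=1e-12)

    def test_ball_volume_bounded_and_converging(self):
        rng = np.random.default_rng(2)
        small = rng.normal(size=(50, 3))
        small /= np.linalg.norm(small, axis=1, keepdims=True)
        big = rng.normal(size=(5000, 3))
        big /= np.linalg.norm(big, axis=1, keepdims=True)
        v_small = mesh_volume(convex_hull(small))
        v_big = mesh_volume(convex_hull(big))
        ball = 4 * np.pi / 3
        assert v_small < v_big < ball
        assert v_big > 0.98 * ball

    def test_coplanar_rejected(self):
        pts = np.column_stack([np.random.default_rng(3).uniform(size=(10, 2)),
                               np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            convex_hull(pts)


class TestFitSphere:
    def test_exact_recovery(self):
        centre = np.array([10.0, -3.0, 2.0])
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1], [0.6, 0.8, 0]])
        pts = centre + 5.0 * dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        c, r, rms = fit_sphere(pts)
        np.testing.assert_allclose(c, centre, atol=1e-9)
        assert r == pytest.approx(5.0, abs=1e-9)
        assert rms < 1e-10

    def test_noisy_radius_within_bound(self):
        rng = np.random.default_rng(4)
        n, radius = 500, 2.0
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sigma = 0.01 * radius
        pts = dirs * radius + rng.normal(0, sigma, (n, 3))
        _, r, _ = fit_sphere(pts)
        assert abs(r - radius) < 3 * sigma / np.sqrt(n) * 3  # generous 3x margin

    def test_coplanar_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError, match="degenerate"):
            fit_sphere(pts)


class TestFitCylinder:
    @staticmethod
    def _cylinder_points(radius=0.03, axis=np.array([0.0, 0.0, 1.0]), n=60):
        ts = np.linspace(-0.1, 0.1, 6)
        phis = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        pts = [radius * np.array([np.cos(p), np.sin(p), 0]) + t * axis
               for t in ts for p in phis]
        return np.asarray(pts)

    def test_exact_recovery(self):
        pts = self._cylinder_points()
        p0, d, r = fit_cylinder(pts)
        assert r == pytest.approx(0.03, abs=1e-9)
        assert abs(abs(d[2]) - 1.0) < 1e-9

    def test_rotation_equivariance(self):
        pts = self._cylinder_points()
        R = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3])[:3, :3]
        _, d, r = fit_cylinder(pts @ R.T)
        expected = R @ np.array([0, 0, 1.0])
        assert r == pytest.approx(0.03, abs=1e-8)
        assert min(np.linalg.norm(d - expected), np.linalg.norm(d + expected)) < 1e-6

    def test_sphere_points_rejected(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(DegenerateGeometryError, match="singular values"):
            fit_cylinder(pts)


class TestScaleAndMirror:
    def test_scale_volume_cubes(self, unit_cube):
        assert mesh_volume(uniform_scale(unit_cube, 2.0)) == pytest.approx(8.0)

    def test_identity_scale(self, unit_cube):
        np.testing.assert_array_equal(
            uniform_scale(unit_cube, 1.0).vertices, unit_cube.vertices)

    def test_scale_about_centroid_fixes_centroid(self, unit_cube):
        c = mesh_centroid(unit_cube)
        np.testing.assert_allclose(
            mesh_centroid(uniform_scale(unit_cube, 0.5, about=c)), c, atol=1e-12)

    def test_nonpositive_factor_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            uniform_scale(unit_cube, -1.0)

    def test_mirror_point(self):
        np.testing.assert_array_equal(mirror_x([0.1, 0.2, 0.3]),
                                      [-0.1, 0.2, 0.3])

    def test_mirror_fixed_plane(self):
        np.testing.assert_array_equal(mirror_x([0.0, 1.0, 2.0]), [0.0, 1.0, 2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(-10, 10, allow_nan=False)] * 3),
                    min_size=1, max_size=8))
    def test_mirror_involution_bitwise(self, pts):
        arr = np.asarray(pts, dtype=float)
        np.testing.assert_array_equal(mirror_x(mirror_x(arr)), arr)
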