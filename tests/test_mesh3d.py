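"""Meshing, smoothing, hole filling, scale calibration and triangle-sum area."""

import numpy as np
import pytest
import trimesh

from lesionmetry.mesh3d import (
    LabeledMesh,
    MeshError,
    ReferenceSegment,
    boundary_loops,
    calibrate_scale,
    measure_area_3d,
    smooth_and_fill,
    triangulate_mesh,
)
from lesionmetry.phantom3d import Surface3D, make_mesh_phantom


def plane_grid_points(n, spacing=1.0, z=0.0):
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    return np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])


def grid_mesh(n, spacing=1.0):
    return triangulate_mesh(plane_grid_points(n, spacing))


def regular_grid_mesh(n, spacing=1.0):
    """Uniform grid with the symmetric one-diagonal split (each interior
    vertex has a balanced 6-neighbourhood, unlike Delaunay's arbitrary
    diagonal choice on the degenerate uniform grid)."""
    idx = np.arange(n * n).reshape(n, n)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    f2 = np.stack([idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    return LabeledMesh(
        plane_grid_points(n, spacing), np.concatenate([f1, f2]), np.zeros(n * n)
    )


class TestTriangulate:
    def test_planar_square_gives_two_triangles(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        mesh = triangulate_mesh(pts)
        assert len(mesh.faces) == 2

    def test_regular_grid_triangle_count(self):
        assert len(grid_mesh(10).faces) == 162  # 2*(n-1)^2

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5), np.arange(5), np.zeros(5)])
        with pytest.raises(MeshError, match="collinear"):
            triangulate_mesh(pts)

    def test_empty_circumcircle_property(self, rng):
        """Delaunay invariant, checked exhaustively against a brute-force
        circumcircle oracle on 50 random planar points."""
        pts2 = rng.random((50, 2)) * 10
        pts = np.column_stack([pts2, np.zeros(50)])
        mesh = triangulate_mesh(pts)
        for tri in mesh.faces:
            a, b, c = pts2[tri]
            # circumcentre by solving the perpendicular-bisector system
            m = 2 * np.array([b - a, c - a])
            rhs = np.array([b @ b - a @ a, c @ c - a @ a])
            center = np.linalg.solve(m, rhs)
            r2 = np.sum((a - center) ** 2)
            others = np.setdiff1d(np.arange(50), tri)
            d2 = np.sum((pts2[others] - center) ** 2, axis=1)
            assert (d2 >= r2 * (1 - 1e-9)).all()


class TestSmoothAndFill:
    def test_flat_plane_is_fixed_point(self):
        mesh = regular_grid_mesh(8)
        out = smooth_and_fill(mesh, iterations=10)
        assert np.abs(out.vertices - mesh.vertices).max() < 1e-9

    def test_noisy_plane_rms_decreases_monotonically(self, rng):
        mesh = regular_grid_mesh(15)
        mesh.vertices[:, 2] += rng.normal(0, 0.05, len(mesh.vertices))
        interior = (
            (mesh.vertices[:, 0] > 0) & (mesh.vertices[:, 0] < 14)
            & (mesh.vertices[:, 1] > 0) & (mesh.vertices[:, 1] < 14)
        )
        rms = []
        for it in range(11):
            v = smooth_and_fill(mesh, iterations=it).vertices
            rms.append(np.sqrt(np.mean(v[interior, 2] ** 2)))
        # decreases monotonically until it reaches the harmonic extension of
        # the (fixed, still-noisy) boundary, and ends far below the start
        assert all(b <= a for a, b in zip(rms[:8], rms[1:8]))
        assert rms[10] < 0.25 * rms[0]

    def test_interior_hole_filled_to_disk_topology(self):
        mesh = grid_mesh(7)
        center = 3 * 7 + 3
        keep = ~np.any(mesh.faces == center, axis=1)
        holed = LabeledMesh(mesh.vertices, mesh.faces[keep], mesh.gray)
        assert len(boundary_loops(holed)) == 2
        filled = smooth_and_fill(holed, iterations=0)
        assert len(boundary_loops(filled)) == 1
        v = len(filled.vertices) - 1  # the unused original centre vertex
        e = len({tuple(sorted(e)) for f in filled.faces for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))})
        f = len(filled.faces)
        assert v - e + f == 1  # Euler characteristic of a disk

    def test_hole_fill_gray_is_loop_mean(self):
        mesh = grid_mesh(7)
        gray = np.zeros(len(mesh.vertices))
        gray[:] = 200.0
        center = 3 * 7 + 3
        keep = ~np.any(mesh.faces == center, axis=1)
        holed = LabeledMesh(mesh.vertices, mesh.faces[keep], gray)
        filled = smooth_and_fill(holed, iterations=0)
        assert filled.gray[-1] == pytest.approx(200.0)


class TestCalibrate:
    def test_scale_from_reference(self):
        mesh = grid_mesh(4)
        ref = ReferenceSegment(np.zeros(3), np.array([2.0, 0, 0]), 4.0)
        out = calibrate_scale(mesh, ref)
        assert out.scale_cm_per_unit == pytest.approx(2.0)

    def test_identity_scale(self):
        mesh = grid_mesh(4)
        ref = ReferenceSegment(np.zeros(3), np.array([1.0, 0, 0]), 1.0)
        assert calibrate_scale(mesh, ref).scale_cm_per_unit == pytest.approx(1.0)

    def test_phantom_reference_recovers_units(self):
        ph = make_mesh_phantom(
            Surface3D(kind="cylinder", radius_cm=19.5), (3.0, 3.0), mesh_units_per_cm=2.7
        )
        mesh = LabeledMesh(ph.vertices, ph.faces, ph.patch_vertex_flags * 255.0)
        ia, ib = ph.reference_vertices
        out = calibrate_scale(
            mesh, ReferenceSegment(mesh.vertices[ia], mesh.vertices[ib], ph.reference_length_cm)
        )
        assert out.scale_cm_per_unit == pytest.approx(1 / 2.7, rel=1e-3)

    def test_zero_length_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSegment(np.zeros(3), np.zeros(3), 1.0)


class TestMeasureArea:
    def unit_triangle(self, grays, scale=1.0):
        mesh = LabeledMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
            np.array([[0, 1, 2]]),
            np.asarray(grays, dtype=float),
            scale_cm_per_unit=scale,
        )
        return measure_area_3d(mesh).total_area_cm2

    def test_white_right_triangle(self):
        assert self.unit_triangle([255, 255, 255]) == pytest.approx(0.5)

    def test_one_white_vertex_excluded(self):
        assert self.unit_triangle([255, 0, 0]) == 0.0

    def test_two_white_vertices_included(self):
        assert self.unit_triangle([255, 255, 0]) == pytest.approx(0.5)

    def test_area_scales_with_square_of_calibration(self):
        assert self.unit_triangle([255] * 3, scale=3.0) == pytest.approx(0.5 * 9.0)

    def test_unscaled_mesh_rejected(self):
        mesh = LabeledMesh(np.eye(3), np.array([[0, 1, 2]]), np.full(3, 255.0))
        with pytest.raises(MeshError, match="scale"):
            measure_area_3d(mesh)

    def test_flat_patch_on_plane_mesh(self):
        ph = make_mesh_phantom(Surface3D(kind="plane"), (3.0, 3.0))
        mesh = LabeledMesh(
            ph.vertices, ph.faces, ph.patch_vertex_flags * 255.0, scale_cm_per_unit=1.0
        )
        assert ph.true_patch_area_cm2 == pytest.approx(9.0)
        assert measure_area_3d(mesh).total_area_cm2 == pytest.approx(9.0, rel=0.01)

    def test_unit_cube_surface_is_six(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        mesh = LabeledMesh(
            np.asarray(box.vertices),
            np.asarray(box.faces),
            np.full(len(box.vertices), 255.0),
            scale_cm_per_unit=1.0,
        )
        assert measure_area_3d(mesh).total_area_cm2 == pytest.approx(6.0)

    def test_sphere_area_within_two_percent(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=3.0)
        assert len(sph.faces) >= 5000
        mesh = LabeledMesh(
            np.asarray(sph.vertices),
            np.asarray(sph.faces),
            np.full(len(sph.vertices), 255.0),
            scale_cm_per_unit=1.0,
        )
        total = measure_area_3d(mesh).total_area_cm2
        assert total == pytest.approx(4 * np.pi * 9.0, rel=0.02)

    def test_rigid_transform_invariance(self, rng):
        ph = make_mesh_phantom(Surface3D(kind="cylinder", radius_cm=8.5), (3.0, 3.0))
        gray = ph.patch_vertex_flags * 255.0
        a = measure_area_3d(LabeledMesh(ph.vertices, ph.faces, gray, 1.0)).total_area_cm2
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = ph.vertices @ rot.T + np.array([5.0, -2.0, 11.0])
        b = measure_area_3d(LabeledMesh(moved, ph.faces, gray, 1.0)).total_area_cm2
        assert a == pytest.approx(b, rel=1e-12)

    def test_whitening_vertices_is_monotone(self, rng):
        ph = make_mesh_phantom(Surface3D(kind="plane"), (3.0, 3.0))
        gray = ph.patch_vertex_flags * 255.0
        base = measure_area_3d(LabeledMesh(ph.vertices, ph.faces, gray, 1.0)).total_area_cm2
        gray2 = gray.copy()
        extra = rng.choice(np.flatnonzero(gray2 == 0), 50, replace=False)
        gray2[extra] = 255.0
        more = measure_area_3d(LabeledMesh(ph.vertices, ph.faces, gray2, 1.0)).total_area_cm2
        assert more >= base


class TestMeshPhantoms:
    @pytest.mark.parametrize("radius, area", [(19.5, 10.8), (19.5, 16.2), (19.5, 21.6),
                                              (8.5, 10.8), (8.5, 16.2)])
    def test_study_cases_constructible(self, radius, area):
        side = float(np.sqrt(area))
        ph = make_mesh_phantom(Surface3D(kind="cylinder", radius_cm=radius), (side, side))
        assert ph.true_patch_area_cm2 == pytest.approx(area)
        assert ph.patch_vertex_flags.sum() > 0

    def test_cylinder_wrapping_preserves_patch_area(self):
        flat = make_mesh_phantom(Surface3D(kind="plane"), (3.0, 4.0))
        bent = make_mesh_phantom(Surface3D(kind="cylinder", radius_cm=8.5), (3.0, 4.0))
        assert flat.true_patch_area_cm2 == bent.true_patch_area_cm2 == 12.0

    def test_sphere_patch_uses_spherical_formula(self):
        r = 10.0
        surf = Surface3D(kind="sphere", radius_cm=r)
        ph = make_mesh_phantom(surf, (3.0, 3.0), resolution_cm=0.1)
        u0, u1, v0, v1 = ph.patch_rect
        expected = r**2 * (u1 - u0) * (np.cos(v0) - np.cos(v1))
        assert ph.true_patch_area_cm2 == pytest.approx(expected)
        # quadrature oracle over the spherical metric
        vs = np.linspace(v0, v1, 2000)
        quad = r**2 * (u1 - u0) * np.trapezoid(np.sin(vs), vs)
        assert ph.true_patch_area_cm2 == pytest.approx(quad, rel=1e-5)

    def test_degenerate_patch_rejected(self):
        with pytest.raises(ValueError):
            make_mesh_phantom(Surface3D(kind="plane"), (0.0, 3.0))

    def test_reference_segment_is_exact_on_cylinder(self):
        ph = make_mesh_phantom(Surface3D(kind="cylinder", radius_cm=8.5), (3.0, 3.0))
        ia, ib = ph.reference_vertices
        d = np.linalg.norm(ph.vertices[ia] - ph.vertices[ib])
        assert d == pytest.approx(ph.reference_length_cm)
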