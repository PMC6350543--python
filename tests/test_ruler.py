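"""Checkerboard-ruler detection: tensors, corners, centerline, pairs."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from lesionmetry.camera import default_camera
from lesionmetry.phantom2d import (
    PhantomSceneSpec,
    RulerSpec,
    SupportSpec,
    centered_shape,
    render_phantom,
)
from lesionmetry.ruler import (
    Centerline,
    CornerSet,
    EdgeLine,
    RulerDetectionError,
    centerline_from_corners,
    classify_checkerboard_corners,
    corner_spacing,
    detect_corners,
    detect_ruler,
    distance_transform,
    find_edge_crossings,
    pair_corresponding_points,
    refine_edge_line,
    structure_tensor_maps,
)


def checkerboard_image(square=20, n=6, lo=30, hi=250):
    tile = (np.indices((n * square, n * square)) // square).sum(0)
    return np.where((tile % 2) == 0, lo, hi).astype(float)


class TestStructureTensor:
    def test_step_edge_has_one_large_eigenvalue(self):
        img = np.zeros((40, 40))
        img[:, 20:] = 200.0
        maps = structure_tensor_maps(img, 1.0, 2.0)
        mid = maps.lam1[20, 18:22]
        assert mid.max() > 100 * max(maps.lam2[20, 18:22].max(), 1e-12)

    def test_checker_corner_has_two_large_eigenvalues(self):
        img = checkerboard_image(square=16, n=2)
        maps = structure_tensor_maps(img, 1.0, 2.0)
        c = 16  # interior corner
        assert maps.lam2[c, c] > 0.2 * maps.lam1[c, c]
        assert maps.lam2[c, c] > 10 * maps.lam2[8, 8]  # flat square centre

    def test_eigenvalues_match_quadratic_formula_oracle(self, rng):
        """Closed-form roots of the characteristic polynomial, recomputed
        independently from the tensor entries at random pixels."""
        img = rng.random((60, 60)) * 255
        gs, ws = 1.0, 2.0
        maps = structure_tensor_maps(img, gs, ws)
        gx = ndimage.gaussian_filter(img, gs, order=(0, 1))
        gy = ndimage.gaussian_filter(img, gs, order=(1, 0))
        axx = ndimage.gaussian_filter(gx * gx, ws)
        axy = ndimage.gaussian_filter(gx * gy, ws)
        ayy = ndimage.gaussian_filter(gy * gy, ws)
        ys = rng.integers(0, 60, 100)
        xs = rng.integers(0, 60, 100)
        for y, x in zip(ys, xs):
            b = axx[y, x] + ayy[y, x]
            c = axx[y, x] * ayy[y, x] - axy[y, x] ** 2
            disc = np.sqrt(max(b * b - 4 * c, 0.0))
            lam1, lam2 = (b + disc) / 2, (b - disc) / 2
            assert maps.lam1[y, x] == pytest.approx(lam1, rel=1e-9, abs=1e-9)
            assert maps.lam2[y, x] == pytest.approx(max(lam2, 0.0), rel=1e-9, abs=1e-9)

    def test_constant_image_yields_zero_tensors(self):
        maps = structure_tensor_maps(np.full((32, 32), 77.0), 1.0, 2.0)
        assert np.allclose(maps.lam1, 0.0, atol=1e-18)


class TestDetectCorners:
    def test_blank_image_gives_empty_set(self):
        maps = structure_tensor_maps(np.zeros((64, 64)), 1.0, 2.0)
        assert len(detect_corners(maps)) == 0

    @pytest.mark.parametrize("n_cols", [4, 8, 16])
    def test_interior_corner_count_and_accuracy(self, n_cols):
        """2*(k-1) interior corners, each within 1 px of the projected
        truth, independent of how many squares are visible."""
        spec = PhantomSceneSpec(
            support=SupportSpec(kind="flat"),
            shape=centered_shape("ellipse", 4.0),
            ruler=RulerSpec(n_cols=n_cols),
            ruler_origin=(-n_cols * 0.25, -4.5),
        )
        img, truth = render_phantom(spec)
        det = detect_ruler(img)
        cb = det["corners"].checkerboard_points
        assert len(cb) == 2 * (n_cols - 1)
        gt = truth.ruler_corner_px.reshape(-1, 2)
        d, _ = cKDTree(cb).query(gt)
        assert d.mean() < 0.5  # projection consistency for noise-free renders
        assert d.max() < 1.0
        assert len(det["pairs"]) == n_cols - 1

    def test_corner_count_invariant_under_rotation(self, flat_phantom):
        image, _ = flat_phantom
        det0 = detect_ruler(image)
        det90 = detect_ruler(np.rot90(image).copy())
        assert int(det90["corners"].is_checkerboard.sum()) == int(
            det0["corners"].is_checkerboard.sum()
        )


class TestClassifyCorners:
    def test_ideal_checker_corner_flagged(self):
        img = checkerboard_image(square=16, n=2)
        corners = CornerSet(np.array([[16.0, 16.0]]))
        out = classify_checkerboard_corners(img, corners, window_px=10)
        assert out.is_checkerboard[0]

    def test_plain_square_corner_rejected(self):
        img = np.full((64, 64), 250.0)
        img[20:44, 20:44] = 30.0  # uniform dark square: 3 similar quadrants
        corners = CornerSet(np.array([[20.0, 20.0]]))
        out = classify_checkerboard_corners(img, corners, window_px=10)
        assert not out.is_checkerboard[0]

    def test_phantom_corners_classified_and_lesion_points_rejected(self, flat_phantom):
        image, truth = flat_phantom
        from lesionmetry.ruler import _to_gray

        maps = structure_tensor_maps(_to_gray(image), 1.0, 3.0)
        raw = detect_corners(maps)
        spacing = corner_spacing(raw.points)
        out = classify_checkerboard_corners(image, raw, window_px=0.6 * spacing)
        cb = out.points[out.is_checkerboard]
        gt = truth.ruler_corner_px.reshape(-1, 2)
        d, _ = cKDTree(cb).query(gt) if len(cb) else (np.full(len(gt), 1e9), None)
        assert (d < 2.0).mean() >= 0.95  # nearly all true corners recovered
        # no flagged point may fall inside the lesion mask
        ys = np.round(cb[:, 1]).astype(int)
        xs = np.round(cb[:, 0]).astype(int)
        assert not truth.shape_mask[ys, xs].any()


class TestCenterline:
    def test_midline_of_two_horizontal_rows(self):
        xs = np.arange(10, 90, 10, dtype=float)
        pts = np.concatenate(
            [np.column_stack([xs, np.full_like(xs, 20.0)]),
             np.column_stack([xs, np.full_like(xs, 30.0)])]
        )
        corners = CornerSet(pts, np.ones(len(pts), dtype=bool))
        cl = centerline_from_corners(corners, (100, 50))
        assert np.abs(cl.samples[:, 1] - 25.0).max() < 0.5

    def test_distance_transform_matches_bruteforce(self, rng):
        pts = rng.random((12, 2)) * np.array([80, 40])
        dt = distance_transform(pts, (80, 40))
        snapped = np.column_stack([np.round(pts[:, 0]), np.round(pts[:, 1])])
        for _ in range(50):
            x = int(rng.integers(0, 80))
            y = int(rng.integers(0, 40))
            brute = np.min(np.hypot(snapped[:, 0] - x, snapped[:, 1] - y))
            assert dt[y, x] == pytest.approx(brute, abs=1e-9)

    def test_arc_rows_give_mid_arc_centerline(self):
        """Rows bent along concentric arcs: the ridge must follow the arc
        midway between them (analytic oracle)."""
        r_mid, gap = 200.0, 10.0
        thetas = np.linspace(np.pi / 2 - 0.35, np.pi / 2 + 0.35, 14)
        center = np.array([150.0, 260.0])
        rows = []
        for r in (r_mid - gap / 2, r_mid + gap / 2):
            rows.append(
                center + np.column_stack([r * np.cos(thetas), -r * np.sin(thetas)])
            )
        pts = np.concatenate(rows)
        corners = CornerSet(pts, np.ones(len(pts), dtype=bool))
        cl = centerline_from_corners(corners, (300, 120))
        d_from_center = np.hypot(*(cl.samples - center).T)
        inner = (cl.arclength > 10) & (cl.arclength < cl.arclength[-1] - 10)
        assert np.abs(d_from_center[inner] - r_mid).max() < 1.0

    def test_single_row_rejected(self):
        xs = np.arange(10, 90, 10, dtype=float)
        pts = np.column_stack([xs, np.full_like(xs, 20.0)])
        corners = CornerSet(pts, np.ones(len(pts), dtype=bool))
        with pytest.raises(RulerDetectionError, match="not separable"):
            centerline_from_corners(corners, (100, 50))


def straight_centerline(y, x0, x1):
    xs = np.arange(x0, x1, 0.5)
    samples = np.column_stack([xs, np.full_like(xs, float(y))])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(samples, axis=0), axis=1))])
    return Centerline(samples=samples, arclength=arc)


class TestEdgeCrossings:
    def test_ideal_alternating_profile_period(self):
        img = np.zeros((40, 200))
        stripe = (np.arange(200) // 20) % 2
        img[:] = np.where(stripe, 250.0, 30.0)[None, :]
        cl = straight_centerline(20, 5, 195)
        crossings = find_edge_crossings(img, cl, min_spacing_px=10)
        xs = np.sort([p[0] for p, _ in crossings])
        assert np.allclose(np.diff(xs), 20.0, atol=0.5)

    def test_constant_profile_rejected(self):
        img = np.full((40, 200), 128.0)
        with pytest.raises(RulerDetectionError):
            find_edge_crossings(img, straight_centerline(20, 5, 195))

    def test_phantom_crossing_count_matches_column_edges(self, flat_phantom, flat_detection):
        # one crossing per interior column edge (plus the two board ends)
        n_cols = 16
        pairs = flat_detection["pairs"]
        assert len(pairs) == n_cols - 1


class TestRefineEdgeLine:
    def make_vertical_edge_maps(self, x_edge=50.0, angle_deg=0.0):
        img = np.zeros((100, 100))
        ys, xs = np.mgrid[0:100, 0:100]
        a = np.deg2rad(angle_deg)
        img[:] = np.where(
            (xs - x_edge) * np.cos(a) + (ys - 50) * np.sin(a) > 0, 250.0, 30.0
        )
        return structure_tensor_maps(img, 1.0, 2.0)

    @pytest.mark.parametrize("angle", [0.0, 30.0])
    def test_recovered_direction(self, angle):
        maps = self.make_vertical_edge_maps(angle_deg=angle)
        line = refine_edge_line(maps, np.array([50.0, 50.0]), radius_px=10)
        want = np.array([-np.sin(np.deg2rad(angle)), np.cos(np.deg2rad(angle))])
        got = line.direction if line.direction @ want > 0 else -line.direction
        assert np.degrees(np.arccos(np.clip(got @ want, -1, 1))) < 1.0

    def test_pca_direction_matches_closed_form(self, rng):
        """The fitted direction equals the dominant eigenvector of the 2x2
        scatter matrix computed by the quadratic formula."""
        maps = self.make_vertical_edge_maps(angle_deg=30.0)
        line = refine_edge_line(maps, np.array([50.0, 50.0]), radius_px=10)
        lam1 = maps.lam1
        ys, xs = np.mgrid[0:100, 0:100]
        inside = (xs - 50.0) ** 2 + (ys - 50.0) ** 2 <= 100
        strong = inside & (lam1 > 0.3 * lam1[inside].max())
        pts = np.column_stack([xs[strong], ys[strong]]).astype(float)
        w = lam1[strong]
        mu = (pts * w[:, None]).sum(0) / w.sum()
        d = pts - mu
        sxx = (w * d[:, 0] ** 2).sum() / w.sum()
        sxy = (w * d[:, 0] * d[:, 1]).sum() / w.sum()
        syy = (w * d[:, 1] ** 2).sum() / w.sum()
        lam = (sxx + syy) / 2 + np.sqrt(((sxx - syy) / 2) ** 2 + sxy**2)
        v = np.array([sxy, lam - sxx])
        v = v / np.linalg.norm(v)
        got = line.direction if line.direction @ v > 0 else -line.direction
        assert np.allclose(got, v, atol=1e-6)

    def test_too_few_edge_pixels_rejected(self):
        maps = structure_tensor_maps(np.zeros((60, 60)), 1.0, 2.0)
        with pytest.raises(RulerDetectionError):
            refine_edge_line(maps, np.array([30.0, 30.0]), radius_px=8)


class TestPairing:
    def test_parallel_rows_give_constant_d(self):
        xs = np.arange(20, 180, 20, dtype=float)
        pts = np.concatenate(
            [np.column_stack([xs, np.full_like(xs, 40.0)]),
             np.column_stack([xs, np.full_like(xs, 80.0)])]
        )
        corners = CornerSet(pts, np.ones(len(pts), dtype=bool))
        lines = [
            EdgeLine(point=np.array([x, 60.0]), direction=np.array([0.0, 1.0]), arclength=x)
            for x in xs
        ]
        pairs = pair_corresponding_points(lines, corners, spacing_px=20.0)
        assert len(pairs) == len(xs)
        for p in pairs:
            assert p.d == pytest.approx(40.0, abs=0.5)
        # ordered left to right along the ruler
        assert all(
            pairs[i].p1[0] < pairs[i + 1].p1[0] for i in range(len(pairs) - 1)
        )

    def test_end_to_end_pair_geometry(self, flat_phantom, flat_detection):
        """Pair separations equal the rendered transverse checker extent."""
        _, truth = flat_phantom
        pairs = flat_detection["pairs"]
        row_a, row_b = truth.ruler_corner_px
        true_d = np.linalg.norm(row_a - row_b, axis=1).mean()
        for p in pairs:
            assert p.d == pytest.approx(true_d, rel=0.02)
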