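"""Flexible checkerboard-ruler detection.

The ruler is a printed strip of three checker rows. Detection proceeds:

1. structure-tensor eigenvalue maps on the grayscale image — one large
   eigenvalue marks edges, two mark corners;
2. corner candidates = non-max-suppressed local maxima of the small
   eigenvalue, refined to sub-pixel;
3. checkerboard classification by comparing the mean intensities of the
   four diagonal window corners around each candidate;
4. the medial centerline between the two corner rows from the ridge of the
   distance transform of the corner points, smoothed by a spline;
5. checker-edge crossings as strong intensity transitions along the
   centerline; each refined to an edge line by PCA over high-eigenvalue
   pixels in a circular window;
6. corresponding corner pairs (p1, p2) across the ruler width by walking
   each edge line to the two corner rows; their separation d is the local
   scale step used for grid extrapolation.

The approach needs no prior knowledge of how many squares are visible.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline
from scipy.signal import find_peaks
from skimage.color import rgb2gray
from skimage.feature import peak_local_max


@dataclass
class TensorMaps:
    """Structure-tensor eigenvalue maps: lam1 >= lam2 >= 0 per pixel."""

    lam1: np.ndarray
    lam2: np.ndarray
    orientation: np.ndarray  # dominant-eigenvector angle, radians


@dataclass
class CornerSet:
    points: np.ndarray  # (N, 2) float, (x, y)
    is_checkerboard: np.ndarray = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.is_checkerboard is None:
            self.is_checkerboard = np.zeros(len(self.points), dtype=bool)

    @property
    def checkerboard_points(self) -> np.ndarray:
        return self.points[self.is_checkerboard]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Centerline:
    """Medial curve of the ruler, densely sampled at ~0.5 px arc steps."""

    samples: np.ndarray  # (M, 2) points
    arclength: np.ndarray  # (M,) cumulative

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.samples, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def point_at(self, s: float) -> np.ndarray:
        x = np.interp(s, self.arclength, self.samples[:, 0])
        y = np.interp(s, self.arclength, self.samples[:, 1])
        return np.array([x, y])


@dataclass
class EdgeLine:
    point: np.ndarray  # a point on the line (PCA centroid)
    direction: np.ndarray  # unit direction along the checker edge
    arclength: float = 0.0  # centerline position of the generating crossing


@dataclass
class CorrespondencePair:
    p1: np.ndarray
    p2: np.ndarray
    arclength: float = 0.0

    @property
    def d(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p2))


class RulerDetectionError(RuntimeError):
    pass


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        return rgb2gray(img.astype(float) / 255.0) * 255.0
    return img.astype(float)


def structure_tensor_maps(
    gray_image: np.ndarray, gradient_sigma: float = 1.0, window_sigma: float = 3.0
) -> TensorMaps:
    """Per-pixel structure tensor and its eigen-decomposition.

    Gradients are Gaussian derivatives at ``gradient_sigma``; the outer
    products are averaged with a Gaussian window of ``window_sigma``. The
    2x2 eigenproblem is solved in closed form.
    """
    g = np.asarray(gray_image, dtype=float)
    if g.ndim != 2:
        raise ValueError("expected a single-channel image")
    gx = ndimage.gaussian_filter(g, gradient_sigma, order=(0, 1))
    gy = ndimage.gaussian_filter(g, gradient_sigma, order=(1, 0))
    axx = ndimage.gaussian_filter(gx * gx, window_sigma)
    axy = ndimage.gaussian_filter(gx * gy, window_sigma)
    ayy = ndimage.gaussian_filter(gy * gy, window_sigma)
    tr = 0.5 * (axx + ayy)
    det_rt = np.sqrt(np.maximum((0.5 * (axx - ayy)) ** 2 + axy**2, 0.0))
    lam1 = tr + det_rt
    lam2 = np.maximum(tr - det_rt, 0.0)
    orientation = 0.5 * np.arctan2(2 * axy, axx - ayy)
    return TensorMaps(lam1=lam1, lam2=lam2, orientation=orientation)


def detect_corners(
    maps: TensorMaps, quality: float = 0.15, min_separation: int = 7
) -> CornerSet:
    """Corners = local maxima of lam2 above ``quality * max(lam2)``.

    Peaks are non-max suppressed at ``min_separation`` and refined to
    sub-pixel by a separable parabolic fit on the 3x3 neighbourhood.
    """
    lam2 = maps.lam2
    if lam2.max() <= 0:
        return CornerSet(np.empty((0, 2)))
    peaks = peak_local_max(
        lam2,
        min_distance=int(min_separation),
        threshold_abs=quality * lam2.max(),
        exclude_border=3,
    )
    pts = []
    for r, c in peaks:
        dr = dc = 0.0
        if 0 < r < lam2.shape[0] - 1:
            denom = lam2[r - 1, c] - 2 * lam2[r, c] + lam2[r + 1, c]
            if denom < 0:
                dr = 0.5 * (lam2[r - 1, c] - lam2[r + 1, c]) / denom
        if 0 < c < lam2.shape[1] - 1:
            denom = lam2[r, c - 1] - 2 * lam2[r, c] + lam2[r, c + 1]
            if denom < 0:
                dc = 0.5 * (lam2[r, c - 1] - lam2[r, c + 1]) / denom
        pts.append([c + np.clip(dc, -0.5, 0.5), r + np.clip(dr, -0.5, 0.5)])
    return CornerSet(np.array(pts).reshape(-1, 2))


def _patch_means(gray: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Bilinear 3x3 patch means at arbitrary (x, y) centres."""
    offs = np.array([-1.0, 0.0, 1.0])
    ox, oy = np.meshgrid(offs, offs)
    xs = centers[:, 0, None] + ox.ravel()[None, :]
    ys = centers[:, 1, None] + oy.ravel()[None, :]
    vals = ndimage.map_coordinates(gray, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    return vals.reshape(len(centers), -1).mean(axis=1)


def classify_checkerboard_corners(
    image: np.ndarray,
    corners: CornerSet,
    window_px: float,
    similar_frac: float = 0.15,
    different_frac: float = 0.25,
) -> CornerSet:
    """Flag corners whose diagonal window-corner intensities alternate.

    At a genuine checkerboard corner the two patches on one diagonal are
    both dark and the two on the other are both light: each diagonal pair
    is internally similar (within ``similar_frac`` of the image intensity
    range) while the pairs differ strongly (more than ``different_frac``).
    """
    gray = _to_gray(image)
    rng_int = float(gray.max() - gray.min())
    if rng_int <= 0 or len(corners) == 0:
        return CornerSet(corners.points, np.zeros(len(corners), dtype=bool))
    h, w = gray.shape
    half = window_px / 2.0
    pts = corners.points
    d_pp = _patch_means(gray, pts + [half, half])
    d_mm = _patch_means(gray, pts + [-half, -half])
    d_pm = _patch_means(gray, pts + [half, -half])
    d_mp = _patch_means(gray, pts + [-half, half])
    inside = (
        (pts[:, 0] - half >= 1)
        & (pts[:, 0] + half <= w - 2)
        & (pts[:, 1] - half >= 1)
        & (pts[:, 1] + half <= h - 2)
    )
    sim1 = np.abs(d_pp - d_mm) < similar_frac * rng_int
    sim2 = np.abs(d_pm - d_mp) < similar_frac * rng_int
    diff = np.abs(0.5 * (d_pp + d_mm) - 0.5 * (d_pm + d_mp)) > different_frac * rng_int
    flags = inside & sim1 & sim2 & diff
    return CornerSet(pts.copy(), flags)


def corner_spacing(points: np.ndarray) -> float:
    """Median nearest-neighbour distance of a point set."""
    from scipy.spatial import cKDTree

    if len(points) < 2:
        raise RulerDetectionError("not enough corners to estimate spacing")
    d, _ = cKDTree(points).query(points, k=2)
    return float(np.median(d[:, 1]))


def distance_transform(points: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest corner point."""
    w, h = image_size
    mask = np.ones((h, w), dtype=bool)
    rr = np.clip(np.round(points[:, 1]).astype(int), 0, h - 1)
    cc = np.clip(np.round(points[:, 0]).astype(int), 0, w - 1)
    mask[rr, cc] = False
    return ndimage.distance_transform_edt(mask)


def centerline_from_corners(
    corners: CornerSet,
    image_size: tuple[int, int],
    sample_step: float = 0.5,
    extend_px: float | None = None,
) -> Centerline:
    """Ruler medial axis from the distance-transform ridge of the corners.

    The ridge is extracted as the per-column maximum of the distance
    transform along the direction transverse to the corner set's principal
    axis, then smoothed with a spline.
    """
    pts = corners.checkerboard_points if corners.is_checkerboard.any() else corners.points
    if len(pts) < 4:
        raise RulerDetectionError("need at least 4 checkerboard corners")
    mean = pts.mean(axis=0)
    cov = np.cov((pts - mean).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    normal = np.array([-axis[1], axis[0]])
    if normal[1] > 0:  # make "upper" (smaller image y) the +normal side
        normal = -normal
    t_all = (pts - mean) @ normal
    if t_all.std() < 0.5:
        raise RulerDetectionError("ruler rows not separable: corners collinear")
    s_all = (pts - mean) @ axis
    dt = distance_transform(pts, image_size)

    t_lo, t_hi = np.percentile(t_all, 10), np.percentile(t_all, 90)
    ts = np.arange(t_lo, t_hi + 0.25, 0.5)
    ss = np.arange(s_all.min(), s_all.max() + 0.5, 1.0)
    grid_s, grid_t = np.meshgrid(ss, ts, indexing="ij")
    px = mean[0] + grid_s * axis[0] + grid_t * normal[0]
    py = mean[1] + grid_s * axis[1] + grid_t * normal[1]
    vals = ndimage.map_coordinates(dt, [py.ravel(), px.ravel()], order=1, mode="nearest")
    vals = vals.reshape(grid_s.shape)
    k = np.argmax(vals, axis=1)
    interior = (k > 0) & (k < len(ts) - 1)
    ridge_s, ridge_t = [], []
    for i in np.flatnonzero(interior):
        j = k[i]
        denom = vals[i, j - 1] - 2 * vals[i, j] + vals[i, j + 1]
        dj = 0.5 * (vals[i, j - 1] - vals[i, j + 1]) / denom if denom < 0 else 0.0
        ridge_s.append(ss[i])
        ridge_t.append(ts[j] + np.clip(dj, -0.5, 0.5) * 0.5)
    if len(ridge_s) < 4:
        raise RulerDetectionError("distance-transform ridge too short")
    ridge_s = np.asarray(ridge_s)
    ridge_t = np.asarray(ridge_t)
    spline = UnivariateSpline(ridge_s, ridge_t, k=3, s=len(ridge_s) * 0.25)
    if extend_px is None:
        # reach the outermost checker edges, which sit half a square past
        # the outermost corner columns
        extend_px = 0.75 * corner_spacing(pts)
    s_dense = np.arange(
        ridge_s.min() - extend_px, ridge_s.max() + extend_px + sample_step / 2, sample_step
    )
    t_dense = spline(s_dense)
    samples = mean + np.outer(s_dense, axis) + np.outer(t_dense, normal)
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(samples=samples, arclength=arclength)


def find_edge_crossings(
    image: np.ndarray,
    centerline: Centerline,
    min_contrast: float = 0.25,
    min_spacing_px: float | None = None,
    smooth_sigma_px: float = 1.5,
) -> list[tuple[np.ndarray, float]]:
    """Checker-edge crossings along the centerline.

    Samples the grayscale profile along the curve, smooths it, and reports
    the sub-pixel arclength of each strong derivative extremum — one per
    intensity transition between adjacent middle-row squares. Returns a
    list of (point, arclength).
    """
    gray = _to_gray(image)
    prof = ndimage.map_coordinates(
        gray, [centerline.samples[:, 1], centerline.samples[:, 0]], order=1, mode="nearest"
    )
    if prof.max() - prof.min() < 1e-9:
        raise RulerDetectionError("ruler period not recoverable: flat profile")
    step = float(np.median(np.diff(centerline.arclength)))
    deriv = ndimage.gaussian_filter1d(prof, smooth_sigma_px / step, order=1)
    mag = np.abs(deriv)
    height = min_contrast * mag.max()
    dist = max(1, int((min_spacing_px or 4.0) / step))
    peaks, _ = find_peaks(mag, height=height, distance=dist)
    out = []
    for p in peaks:
        dp = 0.0
        if 0 < p < len(mag) - 1:
            denom = mag[p - 1] - 2 * mag[p] + mag[p + 1]
            if denom < 0:
                dp = np.clip(0.5 * (mag[p - 1] - mag[p + 1]) / denom, -0.5, 0.5)
        s = float(np.interp(p + dp, np.arange(len(mag)), centerline.arclength))
        out.append((centerline.point_at(s), s))
    if len(out) < 2:
        raise RulerDetectionError("ruler period not recoverable: fewer than 2 crossings")
    return out


def refine_edge_line(
    maps: TensorMaps, crossing: np.ndarray, radius_px: float, lam1_frac: float = 0.3
) -> EdgeLine:
    """Fit the checker edge through a crossing by PCA of high-lam1 pixels
    inside a circular window centred on the crossing."""
    lam1 = maps.lam1
    h, w = lam1.shape
    cx, cy = crossing
    r = int(np.ceil(radius_px))
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    sub = lam1[y0:y1, x0:x1]
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px**2
    strong = inside & (sub > lam1_frac * sub[inside].max())
    n = int(strong.sum())
    if n < 5:
        raise RulerDetectionError("too few edge pixels in window")
    pts = np.column_stack([xs[strong], ys[strong]]).astype(float)
    weights = sub[strong]
    centroid = (pts * weights[:, None]).sum(axis=0) / weights.sum()
    d = pts - centroid
    cov = (d * weights[:, None]).T @ d / weights.sum()
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    return EdgeLine(point=centroid, direction=direction / np.linalg.norm(direction))


def pair_corresponding_points(
    edge_lines: list[EdgeLine],
    corners: CornerSet,
    spacing_px: float | None = None,
    warn: bool = True,
) -> list[CorrespondencePair]:
    """Walk each edge line both ways to the nearest checkerboard corner on
    either corner row; emit (p1, p2) pairs ordered along the ruler."""
    if len(edge_lines) < 2:
        raise RulerDetectionError("need at least 2 edge lines")
    pts = corners.checkerboard_points if corners.is_checkerboard.any() else corners.points
    if len(pts) < 2:
        raise RulerDetectionError("no checkerboard corners to pair")
    if spacing_px is None:
        spacing_px = corner_spacing(pts)
    # consistent "upper" definition across pairs
    ref_normal = None
    pairs = []
    for line in edge_lines:
        rel = pts - line.point
        along = rel @ line.direction
        perp = np.abs(rel @ np.array([-line.direction[1], line.direction[0]]))
        ok = perp < 0.35 * spacing_px
        pos = ok & (along > 0.15 * spacing_px) & (along < 1.2 * spacing_px)
        neg = ok & (along < -0.15 * spacing_px) & (along > -1.2 * spacing_px)
        if not pos.any() or not neg.any():
            if warn:
                _warnings.warn("edge line without corners on both sides; pair dropped")
            continue
        # nearest on each side; ties broken by alignment with the edge direction
        def _pick(idx_mask, sign):
            cand = np.flatnonzero(idx_mask)
            order = np.lexsort((perp[cand], np.abs(along[cand])))
            return pts[cand[order[0]]]

        a = _pick(pos, +1)
        b = _pick(neg, -1)
        if ref_normal is None:
            ref_normal = (a - b) / np.linalg.norm(a - b)
            if ref_normal[1] > 0:
                ref_normal = -ref_normal
        if (a - b) @ ref_normal >= 0:
            p1, p2 = a, b
        else:
            p1, p2 = b, a
        pairs.append(CorrespondencePair(p1=p1, p2=p2, arclength=line.arclength))
    if not pairs:
        raise RulerDetectionError("no correspondence pairs found")
    pairs.sort(key=lambda p: p.arclength)
    # drop duplicates (two crossings snapping to the same corner pair)
    unique = [pairs[0]]
    for p in pairs[1:]:
        if np.linalg.norm(p.p1 - unique[-1].p1) > 0.3 * spacing_px:
            unique.append(p)
    return unique


def detect_ruler(
    image: np.ndarray,
    gradient_sigma: float = 1.0,
    window_sigma: float = 3.0,
    quality: float = 0.15,
    min_separation: int = 7,
) -> dict:
    """Full ruler detection; returns a dict with all intermediate stages.

    Keys: maps, corners, centerline, crossings, edge_lines, pairs.
    """
    gray = _to_gray(image)
    maps = structure_tensor_maps(gray, gradient_sigma, window_sigma)
    raw = detect_corners(maps, quality=quality, min_separation=min_separation)
    if len(raw) < 4:
        raise RulerDetectionError("too few corner candidates")
    spacing0 = corner_spacing(raw.points)
    classified = classify_checkerboard_corners(image, raw, window_px=0.6 * spacing0)
    cb = classified.checkerboard_points
    if len(cb) < 4:
        raise RulerDetectionError("too few checkerboard corners")
    spacing = corner_spacing(cb)
    centerline = centerline_from_corners(classified, (gray.shape[1], gray.shape[0]))
    crossings = find_edge_crossings(
        image, centerline, min_spacing_px=0.5 * spacing
    )
    radius = 0.4 * spacing
    edge_lines = []
    for point, s in crossings:
        try:
            line = refine_edge_line(maps, point, radius)
        except RulerDetectionError:
            _warnings.warn("crossing skipped: too few edge pixels")
            continue
        line.arclength = s
        edge_lines.append(line)
    pairs = pair_corresponding_points(edge_lines, classified, spacing_px=spacing)
    return {
        "maps": maps,
        "corners": classified,
        "centerline": centerline,
        "crossings": crossings,
        "edge_lines": edge_lines,
        "pairs": pairs,
    }
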