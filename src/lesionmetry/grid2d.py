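"""Measurement grid and the per-square area rule.

Each detected correspondence pair (p1, p2) spans one physical checker
square across the ruler width. Extending every pair along its own p1->p2
line with equidistant steps d = ||p1 - p2|| extrapolates the local scale
over the wound; consecutive columns bound quadrilaterals that each map to
one physical square. Every quadrilateral is unwarped by a homography to a
square patch, and the wound area inside it is

    A_w = (N_w / N) * square_edge_cm**2,

with N the total and N_w the wound pixel count of the unwarped patch.
The lesion area is the sum over all grid squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon2mask
from skimage.transform import ProjectiveTransform

from .ruler import CorrespondencePair, detect_ruler
from .seg2d import RoiPolygon, apply_roi, otsu_binarize, predict_probability, threshold_segment


@dataclass
class MeasurementGrid:
    """Quadrilateral lattice: nodes[c, k] is column c, row k (away from ruler)."""

    nodes: np.ndarray  # (n_cols, n_rows+1, 2)
    square_edge_cm: float
    pair_indices: list[int] = field(default_factory=list)

    @property
    def n_quad_cols(self) -> int:
        return self.nodes.shape[0] - 1

    @property
    def n_quad_rows(self) -> int:
        return self.nodes.shape[1] - 1

    def quad(self, c: int, k: int) -> np.ndarray:
        """Corners of quad (c, k), counter-ordered (4, 2)."""
        n = self.nodes
        return np.array([n[c, k], n[c + 1, k], n[c + 1, k + 1], n[c, k + 1]])

    def quads(self):
        for c in range(self.n_quad_cols):
            for k in range(self.n_quad_rows):
                yield (c, k), self.quad(c, k)


@dataclass
class SquareMeasurement:
    N: int
    N_w: int
    A_w: float
    col: int = 0
    row: int = 0


@dataclass
class AreaResult:
    total_area_cm2: float
    per_square: list[SquareMeasurement] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class GridError(RuntimeError):
    pass


def extrapolate_grid(
    pairs: list[CorrespondencePair],
    roi: RoiPolygon,
    square_edge_cm: float,
    max_rows: int = 50,
    margin_rows: int = 1,
) -> MeasurementGrid:
    """Extend every pair's p1->p2 line equidistantly over the ROI.

    Points p3, p4, ... are placed at spacing d = ||p1 - p2|| along each
    line on the wound side; rows continue until the ROI bounding box is
    covered (plus ``margin_rows``), capped at ``max_rows``.
    """
    if len(pairs) < 2:
        raise GridError("need at least 2 correspondence pairs")
    centroid = roi.centroid
    # orient all pairs so p2 is the wound-side corner row (majority vote)
    votes = [np.dot(centroid - np.asarray(p.p2), np.asarray(p.p2) - np.asarray(p.p1)) for p in pairs]
    flip = np.median(votes) < 0
    starts, dirs, ds = [], [], []
    for p in pairs:
        a, b = (np.asarray(p.p2), np.asarray(p.p1)) if flip else (np.asarray(p.p1), np.asarray(p.p2))
        d = np.linalg.norm(b - a)
        if d <= 0:
            raise GridError("degenerate pair with zero separation")
        starts.append(b)
        dirs.append((b - a) / d)
        ds.append(d)
    bbox = np.array(
        [
            roi.vertices.min(axis=0),
            [roi.vertices[:, 0].min(), roi.vertices[:, 1].max()],
            roi.vertices.max(axis=0),
            [roi.vertices[:, 0].max(), roi.vertices[:, 1].min()],
        ]
    )
    k_needed = 0
    for s, u, d in zip(starts, dirs, ds):
        proj = (bbox - s) @ u / d
        k_needed = max(k_needed, int(np.ceil(proj.max())))
    if k_needed <= 0:
        raise GridError("ROI lies on the ruler side; grid cannot cover it")
    n_rows = min(k_needed + margin_rows, max_rows)
    nodes = np.empty((len(pairs), n_rows + 1, 2))
    for i, (s, u, d) in enumerate(zip(starts, dirs, ds)):
        ks = np.arange(n_rows + 1)[:, None]
        nodes[i] = s + ks * d * u
    return MeasurementGrid(
        nodes=nodes, square_edge_cm=square_edge_cm, pair_indices=list(range(len(pairs)))
    )


def _quad_area(quad: np.ndarray) -> float:
    x, y = quad[:, 0], quad[:, 1]
    return 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _is_convex(quad: np.ndarray) -> bool:
    v = np.roll(quad, -1, axis=0) - quad
    cross = v[:, 0] * np.roll(v, -1, axis=0)[:, 1] - v[:, 1] * np.roll(v, -1, axis=0)[:, 0]
    return bool(np.all(cross > 0) or np.all(cross < 0))


def detect_degenerate_grid(grid: MeasurementGrid, wound_mask: np.ndarray) -> list[str]:
    """Warnings for converging grid columns and wound pixels off the grid."""
    out = []
    for c in range(grid.n_quad_cols):
        first = abs(_quad_area(grid.quad(c, 0)))
        if first <= 0:
            out.append(f"converging grid: column {c} starts degenerate")
            continue
        for k in range(grid.n_quad_rows):
            if abs(_quad_area(grid.quad(c, k))) < 0.25 * first:
                out.append(f"converging grid: column {c} collapses by row {k}")
                break
    n = grid.nodes
    boundary = np.concatenate([n[:, 0], n[-1, 1:], n[-2::-1, -1], n[0, -2:0:-1]])
    footprint = polygon2mask(wound_mask.shape, boundary[:, ::-1])
    outside = wound_mask & ~footprint
    if outside.any():
        out.append(f"wound outside the grid: {int(outside.sum())} px not covered")
    return out


def homography_from_quad(quad: np.ndarray, out_size_px: int) -> ProjectiveTransform:
    """Homography mapping the output square [0, out]^2 onto the quad."""
    s = float(out_size_px)
    src = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float)
    t = ProjectiveTransform.from_estimate(src, np.asarray(quad, dtype=float))
    if not t:
        raise GridError("homography estimation failed")
    return t


def unwarp_quadrilateral(mask: np.ndarray, quad: np.ndarray, out_size_px: int) -> np.ndarray:
    """Map the quad region of ``mask`` onto a square patch (nearest-neighbour).

    Samples are taken at output-cell centres so that adjacent quads tile
    the mask without double counting or boundary loss.
    """
    quad = np.asarray(quad, dtype=float)
    if not _is_convex(quad):
        raise GridError("non-convex quadrilateral")
    t = homography_from_quad(quad, out_size_px)
    gx, gy = np.meshgrid(np.arange(out_size_px) + 0.5, np.arange(out_size_px) + 0.5)
    pts = t(np.column_stack([gx.ravel(), gy.ravel()]).astype(float))
    vals = ndimage.map_coordinates(
        np.asarray(mask, dtype=float), [pts[:, 1], pts[:, 0]], order=0, mode="constant"
    )
    return vals.reshape(out_size_px, out_size_px) > 0.5


def square_wound_area(patch: np.ndarray, square_edge_cm: float) -> SquareMeasurement:
    """Pixel-fraction area rule: A_w = (N_w / N) * square area."""
    patch = np.asarray(patch)
    n = int(patch.size)
    if n == 0:
        raise GridError("empty unwarped patch")
    n_w = int(np.count_nonzero(patch))
    return SquareMeasurement(N=n, N_w=n_w, A_w=(n_w / n) * square_edge_cm**2)


def _owner_map(grid: MeasurementGrid, shape: tuple[int, int]) -> np.ndarray:
    """Assign each pixel to one quad (nearest centre where quads overlap)."""
    owner = np.full(shape, -1, dtype=np.int32)
    best = np.full(shape, np.inf)
    for qi, ((c, k), quad) in enumerate(grid.quads()):
        rr, cc = draw_polygon(quad[:, 1], quad[:, 0], shape=shape)
        if len(rr) == 0:
            continue
        center = quad.mean(axis=0)
        dist = (rr - center[1]) ** 2 + (cc - center[0]) ** 2
        take = dist < best[rr, cc]
        owner[rr[take], cc[take]] = qi
        best[rr[take], cc[take]] = dist[take]
    return owner


def grid_wound_area(
    wound_mask: np.ndarray, grid: MeasurementGrid, out_size_px: int | None = None
) -> AreaResult:
    """Sum the area rule over all grid squares; overlap resolved by quad ownership."""
    edges = np.linalg.norm(grid.nodes[1:, 0] - grid.nodes[:-1, 0], axis=1)
    median_edge = float(np.median(edges)) if len(edges) else 16.0
    if out_size_px is None:
        out_size_px = max(16, int(round(median_edge)))
    warnings = detect_degenerate_grid(grid, wound_mask)
    owner = _owner_map(grid, wound_mask.shape)
    per_square = []
    total = 0.0
    for qi, ((c, k), quad) in enumerate(grid.quads()):
        if not _is_convex(quad):
            warnings.append(f"skipped non-convex quad ({c},{k})")
            continue
        owned = wound_mask & (owner == qi)
        if not owned.any():
            continue
        patch = unwarp_quadrilateral(owned, quad, out_size_px)
        m = square_wound_area(patch, grid.square_edge_cm)
        m.col, m.row = c, k
        per_square.append(m)
        total += m.A_w
    return AreaResult(total_area_cm2=total, per_square=per_square, warnings=warnings)


def measure_area_2d(
    image: np.ndarray,
    roi: RoiPolygon,
    square_edge_cm: float,
    model=None,
    threshold: float | None = None,
    invert: bool = True,
    detect_kwargs: dict | None = None,
) -> AreaResult:
    """Full 2D pipeline: segment, detect the ruler, extrapolate, sum the area rule.

    Segmentation uses the random-forest ``model`` if given, otherwise a
    plain intensity ``threshold`` (the phantom-evaluation mode).
    """
    if model is None and threshold is None:
        raise ValueError("provide a trained model or a threshold")
    if model is not None:
        prob = predict_probability(model, image)
        mask = otsu_binarize(prob)
    else:
        mask = threshold_segment(image, threshold, invert=invert)
    wound = apply_roi(mask, roi)
    det = detect_ruler(image, **(detect_kwargs or {}))
    grid = extrapolate_grid(det["pairs"], roi, square_edge_cm)
    return grid_wound_area(wound, grid)
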