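"""Meshing, smoothing and mesh-based area measurement.

The sparse cloud is triangulated in 2.5D (planar Delaunay over the
best-fit plane), Laplacian-smoothed with fixed boundary, interior holes
are fan-filled, the metric scale comes from a reference segment of known
physical length, and the wound area is the sum of areas of triangles with
at least two vertices whose reconstructed mask gray value exceeds 127.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import Delaunay

from .grid2d import AreaResult


@dataclass
class LabeledMesh:
    """Triangle mesh with per-vertex gray labels and an optional metric scale."""

    vertices: np.ndarray  # (N, 3) mesh units
    faces: np.ndarray  # (M, 3) int
    gray: np.ndarray  # (N,) in [0, 255]
    scale_cm_per_unit: float | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.gray = np.asarray(self.gray, dtype=float)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a missing vertex")

    def face_areas(self) -> np.ndarray:
        """Triangle areas in mesh units squared (cross-product rule)."""
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


@dataclass
class ReferenceSegment:
    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    true_length_cm: float

    def __post_init__(self):
        self.endpoint_a = np.asarray(self.endpoint_a, dtype=float)
        self.endpoint_b = np.asarray(self.endpoint_b, dtype=float)
        if self.true_length_cm <= 0:
            raise ValueError("reference length must be positive")
        if np.allclose(self.endpoint_a, self.endpoint_b):
            raise ValueError("reference endpoints coincide")


class MeshError(RuntimeError):
    pass


def triangulate_mesh(cloud_or_points, gray: np.ndarray | None = None) -> LabeledMesh:
    """2.5D Delaunay: project points onto their best-fit plane, triangulate
    there, and lift the connectivity back to 3D."""
    if hasattr(cloud_or_points, "points"):
        pts = np.asarray(cloud_or_points.points, dtype=float)
        if gray is None:
            gray = getattr(cloud_or_points, "gray", None)
    else:
        pts = np.asarray(cloud_or_points, dtype=float)
    if gray is None:
        gray = np.zeros(len(pts))
    if len(pts) < 3:
        raise MeshError("need at least 3 points")
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise MeshError("points are collinear; no surface to triangulate")
    plane2d = (pts - center) @ vt[:2].T
    tri = Delaunay(plane2d)
    return LabeledMesh(vertices=pts, faces=tri.simplices, gray=np.asarray(gray, dtype=float))


def _edge_counts(faces: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            counts[(min(a, b), max(a, b))] += 1
    return counts


def boundary_loops(mesh: LabeledMesh) -> list[list[int]]:
    """Closed vertex loops of boundary edges (edges used by one face)."""
    counts = _edge_counts(mesh.faces)
    nbrs: dict[int, list[int]] = defaultdict(list)
    for (a, b), c in counts.items():
        if c == 1:
            nbrs[a].append(b)
            nbrs[b].append(a)
    loops = []
    seen: set[int] = set()
    for start in list(nbrs):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = [n for n in nbrs[cur] if n != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                break
            loop.append(cur)
            seen.add(cur)
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def smooth_and_fill(
    mesh: LabeledMesh,
    iterations: int = 10,
    lambda_factor: float = 0.5,
    hole_loop_fraction: float = 0.75,
) -> LabeledMesh:
    """Laplacian smoothing (boundary fixed) followed by interior hole filling.

    Each interior vertex moves toward the mean of its 1-ring neighbours by
    ``lambda_factor`` per iteration, which removes the spurious surface
    area contributed by reconstruction noise. Boundary loops shorter than
    ``hole_loop_fraction`` of the longest loop are treated as holes and
    fan-filled from their centroid; the new vertex inherits the mean gray
    of the loop.
    """
    from scipy import sparse

    v = mesh.vertices.copy()
    faces = mesh.faces
    counts = _edge_counts(faces)
    edges = np.array(list(counts.keys()))
    adj = sparse.coo_matrix(
        (np.ones(2 * len(edges)), (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(len(v), len(v)),
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    boundary_v = np.zeros(len(v), dtype=bool)
    for (a, b), c in counts.items():
        if c == 1:
            boundary_v[a] = boundary_v[b] = True
    movable = (deg > 0) & ~boundary_v
    safe_deg = np.maximum(deg, 1.0)[:, None]
    for _ in range(iterations):
        disp = lambda_factor * (adj @ v / safe_deg - v)
        v[movable] += disp[movable]
    out = LabeledMesh(v, faces.copy(), mesh.gray.copy(), mesh.scale_cm_per_unit)

    loops = boundary_loops(out)
    if len(loops) > 1:
        lengths = []
        for loop in loops:
            p = out.vertices[loop]
            lengths.append(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())
        longest = max(lengths)
        new_verts, new_gray, new_faces = [out.vertices], [out.gray], [out.faces]
        nv = len(out.vertices)
        for loop, length in zip(loops, lengths):
            if length >= hole_loop_fraction * longest:
                continue
            centroid = out.vertices[loop].mean(axis=0)
            g = out.gray[loop].mean()
            new_verts.append(centroid[None])
            new_gray.append(np.array([g]))
            fan = np.array([[loop[i], loop[(i + 1) % len(loop)], nv] for i in range(len(loop))])
            new_faces.append(fan)
            nv += 1
        out = LabeledMesh(
            np.concatenate(new_verts),
            np.concatenate(new_faces),
            np.concatenate(new_gray),
            out.scale_cm_per_unit,
        )
    return out


def calibrate_scale(mesh: LabeledMesh, ref: ReferenceSegment) -> LabeledMesh:
    """Set the metric scale from a segment of known physical length."""
    d = np.linalg.norm(ref.endpoint_a - ref.endpoint_b)
    if d <= 0:
        raise MeshError("zero-length reference segment")
    return replace(mesh, scale_cm_per_unit=ref.true_length_cm / d)


def measure_area_3d(mesh: LabeledMesh, gray_threshold: float = 127.0) -> AreaResult:
    """Sum of triangle areas with >= 2 vertices whiter than the threshold,
    scaled to cm^2 by the calibrated metric factor."""
    if mesh.scale_cm_per_unit is None:
        raise MeshError("mesh has no metric scale; run calibrate_scale first")
    white = mesh.gray > gray_threshold
    n_white = white[mesh.faces].sum(axis=1)
    areas = mesh.face_areas()
    total = float(areas[n_white >= 2].sum() * mesh.scale_cm_per_unit**2)
    return AreaResult(total_area_cm2=total, per_square=[], warnings=[])


def measure_pipeline_3d(
    frames,
    masks,
    intrinsics,
    reference,
    stride: int = 1,
    gray_threshold: float = 127.0,
    seed: int = 0,
    filter_kwargs: dict | None = None,
) -> AreaResult:
    """End-to-end 3D pipeline from an image sequence plus mask sequence.

    ``reference`` is either a :class:`ReferenceSegment` with endpoints in
    reconstruction units, or ``("camera_baseline", i, j, length_cm)``
    using the known physical distance between two camera positions of the
    trajectory as the reference length.
    """
    from . import recon3d

    seq = recon3d.extract_frames(frames, stride=stride, masks=masks)
    cloud = recon3d.sparse_reconstruct(seq, intrinsics, seed=seed)
    cloud = recon3d.filter_isolated_points(cloud, **(filter_kwargs or {}))
    cloud = recon3d.colorize_cloud(cloud, seq.frames)
    cloud = recon3d.mask_colorize_cloud(cloud, seq.masks)
    mesh = triangulate_mesh(cloud)
    mesh = smooth_and_fill(mesh)
    if isinstance(reference, tuple) and reference[0] == "camera_baseline":
        _, i, j, length_cm = reference
        ci = cloud.camera_center(i)
        cj = cloud.camera_center(j)
        ref = ReferenceSegment(ci, cj, length_cm)
    else:
        ref = reference
    mesh = calibrate_scale(mesh, ref)
    return measure_area_3d(mesh, gray_threshold=gray_threshold)
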