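"""Sparse structure-from-motion reconstruction.

SIFT features per frame, ratio-test matching between consecutive frames,
RANSAC on the essential matrix for geometric verification, two-view
initialisation on the most consistent pair, then incremental pose
estimation (reprojection-based refinement seeded from the neighbouring
pose) and linear multi-view triangulation. The result is a sparse point
cloud with per-point observation tracks, colours and camera poses, defined
up to a global similarity; metric scale is recovered later from a
reference length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import EssentialMatrixTransform


class ReconstructionError(RuntimeError):
    pass


@dataclass
class FrameSequence:
    frames: list
    masks: list | None = None
    indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ReconstructionError("need at least 2 frames")
        shape0 = np.asarray(self.frames[0]).shape
        for f in self.frames:
            if np.asarray(f).shape != shape0:
                raise ReconstructionError("frames must share one image size")
        if not self.indices:
            self.indices = list(range(len(self.frames)))


@dataclass
class SparseCloud:
    points: np.ndarray  # (N, 3), arbitrary scale
    tracks: list  # per point: list of (frame_index, (x, y))
    colors: np.ndarray | None = None  # (N, 3) in [0, 255]
    gray: np.ndarray | None = None  # (N,) in [0, 255]
    poses: list | None = None  # per frame: (R, t) with x_cam = R x + t, or None

    def camera_center(self, i: int) -> np.ndarray:
        r, t = self.poses[i]
        return -r.T @ t

    def __len__(self) -> int:
        return len(self.points)


def extract_frames(source, stride: int = 1, masks=None) -> FrameSequence:
    """Ordered, de-duplicated frames from a directory of numbered images or
    a list of arrays, subsampled by ``stride``."""
    if isinstance(source, (str, Path)):
        from PIL import Image

        paths = sorted(Path(source).glob("*.png")) + sorted(Path(source).glob("*.jpg"))
        if not paths:
            raise ReconstructionError(f"no frames found in {source}")
        frames = [np.asarray(Image.open(p).convert("RGB")) for p in paths]
    else:
        frames = [np.asarray(f) for f in source]
    frames = frames[:: max(1, int(stride))]
    if masks is not None:
        masks = [np.asarray(m) for m in masks][:: max(1, int(stride))]
    # drop exact consecutive duplicates
    kept, kept_masks, kept_idx = [], [], []
    for i, f in enumerate(frames):
        if kept and f.shape == kept[-1].shape and np.array_equal(f, kept[-1]):
            continue
        kept.append(f)
        kept_idx.append(i)
        if masks is not None:
            kept_masks.append(masks[i])
    return FrameSequence(frames=kept, masks=kept_masks if masks is not None else None,
                         indices=kept_idx)


def _intrinsics(intrinsics) -> tuple[float, float, float]:
    if hasattr(intrinsics, "focal_length_px"):
        f = intrinsics.focal_length_px
        cx, cy = intrinsics.principal_point
        return float(f), float(cx), float(cy)
    k = np.asarray(intrinsics, dtype=float)
    if k.shape == (3, 3):
        return float(k[0, 0]), float(k[0, 2]), float(k[1, 2])
    raise ValueError("intrinsics must be a CameraModel or 3x3 matrix")


def _triangulate_linear(obs: list[tuple[np.ndarray, np.ndarray, np.ndarray]]) -> np.ndarray:
    """Linear multi-view triangulation from (R, t, normalized xy) tuples."""
    rows = []
    for r, t, xy in obs:
        p = np.hstack([r, t[:, None]])
        rows.append(xy[0] * p[2] - p[0])
        rows.append(xy[1] * p[2] - p[1])
    a = np.asarray(rows)
    _, _, vt = np.linalg.svd(a)
    x = vt[-1]
    return x[:3] / x[3]


def _project_normalized(r, t, pts):
    cam = pts @ r.T + t
    return cam[:, :2] / cam[:, 2:3], cam[:, 2]


def _decompose_essential(e, x1, x2):
    """Relative pose (R, t) from an essential matrix with cheirality check."""
    u, _, vt = np.linalg.svd(e)
    if np.linalg.det(u) < 0:
        u = -u
    if np.linalg.det(vt) < 0:
        vt = -vt
    w = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
    best, best_count = None, -1
    for r in (u @ w @ vt, u @ w.T @ vt):
        for t in (u[:, 2], -u[:, 2]):
            count = 0
            for a, b in zip(x1[:50], x2[:50]):
                x = _triangulate_linear([(np.eye(3), np.zeros(3), a), (r, t, b)])
                z1 = x[2]
                z2 = (r @ x + t)[2]
                if z1 > 0 and z2 > 0:
                    count += 1
            if count > best_count:
                best, best_count = (r, t), count
    if best_count <= 0:
        raise ReconstructionError("essential-matrix decomposition found no valid pose")
    return best


def _refine_pose(r0, t0, pts3d, xy_norm):
    rv0 = Rotation.from_matrix(r0).as_rotvec()

    def resid(params):
        r = Rotation.from_rotvec(params[:3]).as_matrix()
        proj, z = _project_normalized(r, params[3:], pts3d)
        res = (proj - xy_norm).ravel()
        res[np.repeat(z <= 1e-9, 2)] = 1.0
        return res

    sol = least_squares(resid, np.r_[rv0, t0], loss="soft_l1", f_scale=0.005, max_nfev=200)
    return Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:]


def sparse_reconstruct(
    frames: FrameSequence,
    intrinsics,
    seed: int = 0,
    min_inliers: int = 8,
    max_reproj_px: float = 2.0,
    ransac_trials: int = 1000,
) -> SparseCloud:
    """Incremental SfM over consecutive frames.

    Raises :class:`ReconstructionError` when a consecutive pair has fewer
    than ``min_inliers`` verified matches or no measurable parallax.
    """
    f, cx, cy = _intrinsics(intrinsics)
    grays = [rgb2gray(np.asarray(fr).astype(float) / 255.0) for fr in frames.frames]
    sift = SIFT()
    kps, descs = [], []
    for g in grays:
        try:
            sift.detect_and_extract(g)
        except RuntimeError as exc:  # SIFT found no features
            raise ReconstructionError(f"insufficient texture: {exc}") from exc
        kps.append(sift.keypoints[:, ::-1].astype(float))  # (x, y)
        descs.append(sift.descriptors.copy())
    n_frames = len(grays)
    pair_matches = []
    for i in range(n_frames - 1):
        m = match_descriptors(descs[i], descs[i + 1], cross_check=True, max_ratio=0.8)
        if len(m) < min_inliers:
            raise ReconstructionError(
                f"insufficient parallax/texture: {len(m)} matches between frames {i} and {i+1}"
            )
        flow = np.linalg.norm(kps[i][m[:, 0]] - kps[i + 1][m[:, 1]], axis=1)
        if np.median(flow) < 0.25:
            raise ReconstructionError("insufficient parallax: frames nearly identical")
        pair_matches.append(m)

    def norm(xy):
        return (xy - [cx, cy]) / f

    inlier_sets, models = [], []
    for i, m in enumerate(pair_matches):
        src = norm(kps[i][m[:, 0]])
        dst = norm(kps[i + 1][m[:, 1]])
        try:
            model, inl = ransac(
                (src, dst),
                EssentialMatrixTransform,
                min_samples=8,
                residual_threshold=1.5 / f,
                max_trials=ransac_trials,
                rng=seed,
            )
        except Exception as exc:  # degenerate geometry
            raise ReconstructionError(f"essential-matrix RANSAC failed: {exc}") from exc
        if model is None or inl is None or inl.sum() < min_inliers:
            raise ReconstructionError(
                f"insufficient parallax/texture between frames {i} and {i+1}"
            )
        inlier_sets.append(np.asarray(inl, dtype=bool))
        models.append(model)

    # initialise on the consecutive pair with the best combination of
    # verified matches and parallax
    flows = [
        np.median(np.linalg.norm(kps[i][m[:, 0]] - kps[i + 1][m[:, 1]], axis=1))
        for i, m in enumerate(pair_matches)
    ]
    i0 = int(np.argmax([s.sum() * fl for s, fl in zip(inlier_sets, flows)]))
    poses: list = [None] * n_frames
    poses[i0] = (np.eye(3), np.zeros(3))
    m, inl = pair_matches[i0], inlier_sets[i0]
    x1 = norm(kps[i0][m[inl, 0]])
    x2 = norm(kps[i0 + 1][m[inl, 1]])
    r, t = _decompose_essential(models[i0].params, x1, x2)
    poses[i0 + 1] = (r, t)

    points: list[np.ndarray] = []
    tracks: list[list] = []
    feat_to_point: list[dict[int, int]] = [dict() for _ in range(n_frames)]

    def add_point(obs_frames, obs_feats):
        obs = [(poses[fi][0], poses[fi][1], norm(kps[fi][ft][None])[0]) for fi, ft in zip(obs_frames, obs_feats)]
        x = _triangulate_linear(obs)
        for fi, ft in zip(obs_frames, obs_feats):
            r_, t_ = poses[fi]
            proj, z = _project_normalized(r_, t_, x[None])
            if z[0] <= 1e-9:
                return
            err = np.linalg.norm(proj[0] - norm(kps[fi][ft][None])[0]) * f
            if err > max_reproj_px:
                return
        pid = len(points)
        points.append(x)
        tracks.append([(fi, tuple(kps[fi][ft])) for fi, ft in zip(obs_frames, obs_feats)])
        for fi, ft in zip(obs_frames, obs_feats):
            feat_to_point[fi][ft] = pid

    for a, b in zip(m[inl, 0], m[inl, 1]):
        add_point([i0, i0 + 1], [a, b])
    if len(points) < 8:
        raise ReconstructionError("two-view initialisation produced too few points")

    order = list(range(i0 + 2, n_frames)) + list(range(i0 - 1, -1, -1))
    for j in order:
        i = j - 1 if j > i0 else j + 1  # already-registered neighbour
        if j > i0:
            m, inl = pair_matches[j - 1], inlier_sets[j - 1]
            feats_i, feats_j = m[inl, 0], m[inl, 1]
        else:
            m, inl = pair_matches[j], inlier_sets[j]
            feats_i, feats_j = m[inl, 1], m[inl, 0]
        known = [(fi_, fj_) for fi_, fj_ in zip(feats_i, feats_j) if fi_ in feat_to_point[i]]
        if len(known) < 6:
            raise ReconstructionError(f"too few 2D-3D correspondences to register frame {j}")
        pts3d = np.array([points[feat_to_point[i][fi_]] for fi_, _ in known])
        xy = norm(kps[j][[fj_ for _, fj_ in known]])
        r0, t0 = poses[i]
        r, t = _refine_pose(r0, t0, pts3d, xy)
        poses[j] = (r, t)
        for (fi_, fj_) in known:
            pid = feat_to_point[i][fi_]
            feat_to_point[j][fj_] = pid
            tracks[pid].append((j, tuple(kps[j][fj_])))
        for fi_, fj_ in zip(feats_i, feats_j):
            if fi_ not in feat_to_point[i]:
                add_point([i, j], [fi_, fj_])

    pts = np.asarray(points)
    # alternate full-track retriangulation with per-pose refinement to pull
    # out the drift of the incremental chain (Gauss-Seidel style, poses and
    # points only — no joint bundle adjustment)
    for _ in range(3):
        for pid, track in enumerate(tracks):
            if len(track) > 2:
                obs = [(poses[fi][0], poses[fi][1], norm(np.array(xy)[None])[0]) for fi, xy in track]
                pts[pid] = _triangulate_linear(obs)
        frame_obs: list[list] = [[] for _ in range(n_frames)]
        for pid, track in enumerate(tracks):
            for fi, xy in track:
                frame_obs[fi].append((pid, xy))
        for fi in range(n_frames):
            if fi == i0 or len(frame_obs[fi]) < 6:
                continue  # keep the gauge frame fixed
            pids = [pid for pid, _ in frame_obs[fi]]
            xy = norm(np.array([xy_ for _, xy_ in frame_obs[fi]]))
            r_, t_ = _refine_pose(poses[fi][0], poses[fi][1], pts[pids], xy)
            poses[fi] = (r_, t_)
    # merge duplicate landmarks: SIFT emits one keypoint per orientation at
    # a corner, so distinct tracks can observe the same physical point
    parent = list(range(len(pts)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    from collections import defaultdict

    bins: dict = defaultdict(list)
    for pid, track in enumerate(tracks):
        for fi, (x, y) in track:
            bins[(fi, round(x), round(y))].append(pid)
    for group in bins.values():
        for other in group[1:]:
            ra, rb = find(group[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    merged: dict = defaultdict(list)
    for pid in range(len(pts)):
        merged[find(pid)].append(pid)
    new_pts, new_tracks = [], []
    for group in merged.values():
        new_pts.append(pts[group].mean(axis=0))
        track = []
        seen_frames = set()
        for pid in group:
            for fi, xy in tracks[pid]:
                if fi not in seen_frames:
                    track.append((fi, xy))
                    seen_frames.add(fi)
        new_tracks.append(sorted(track))
    pts = np.asarray(new_pts)
    tracks = new_tracks
    for pid, track in enumerate(tracks):
        if len(track) > 2:
            obs = [(poses[fi][0], poses[fi][1], norm(np.array(xy)[None])[0]) for fi, xy in track]
            pts[pid] = _triangulate_linear(obs)

    keep = []
    for pid, track in enumerate(tracks):
        errs = []
        ok = True
        for fi, xy in track:
            r_, t_ = poses[fi]
            proj, z = _project_normalized(r_, t_, pts[pid][None])
            if z[0] <= 1e-9:
                ok = False
                break
            errs.append(np.linalg.norm(proj[0] - norm(np.array(xy)[None])[0]) * f)
        if ok and np.mean(errs) <= max_reproj_px:
            keep.append(pid)
    if not keep:
        raise ReconstructionError("no points survived reprojection filtering")
    return SparseCloud(
        points=pts[keep],
        tracks=[tracks[pid] for pid in keep],
        colors=None,
        gray=None,
        poses=poses,
    )


def filter_isolated_points(
    cloud: SparseCloud, radius: float | None = None, min_neighbors: int = 5
) -> SparseCloud:
    """Keep points with at least ``min_neighbors`` others within ``radius``
    (default: twice the median nearest-neighbour distance)."""
    if min_neighbors <= 0:
        return cloud
    pts = cloud.points
    tree = cKDTree(pts)
    if radius is None:
        d, _ = tree.query(pts, k=2)
        radius = 2.0 * float(np.median(d[:, 1]))
    if radius <= 0:
        raise ValueError("radius must be positive")
    counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in pts])
    keep = counts >= min_neighbors
    if not keep.any():
        raise ReconstructionError("over-aggressive filtering removed every point")
    return SparseCloud(
        points=pts[keep],
        tracks=[t for t, k in zip(cloud.tracks, keep) if k],
        colors=None if cloud.colors is None else cloud.colors[keep],
        gray=None if cloud.gray is None else cloud.gray[keep],
        poses=cloud.poses,
    )


def _mean_track_values(cloud: SparseCloud, images: list, channels: int) -> tuple[np.ndarray, np.ndarray]:
    vals = np.zeros((len(cloud), channels))
    ok = np.zeros(len(cloud), dtype=bool)
    for pid, track in enumerate(cloud.tracks):
        acc = []
        for fi, (x, y) in track:
            img = np.asarray(images[fi])
            xi, yi = int(round(x)), int(round(y))
            if 0 <= yi < img.shape[0] and 0 <= xi < img.shape[1]:
                v = img[yi, xi]
                acc.append(np.atleast_1d(v).astype(float)[:channels])
        if acc:
            vals[pid] = np.mean(acc, axis=0)
            ok[pid] = True
    return vals, ok


def colorize_cloud(cloud: SparseCloud, frames: list) -> SparseCloud:
    """Point colour = mean RGB over the point's track observations."""
    vals, ok = _mean_track_values(cloud, frames, 3)
    if not ok.all():
        cloud = SparseCloud(
            points=cloud.points[ok],
            tracks=[t for t, k in zip(cloud.tracks, ok) if k],
            poses=cloud.poses,
        )
        vals = vals[ok]
    return SparseCloud(
        points=cloud.points, tracks=cloud.tracks, colors=vals, gray=cloud.gray, poses=cloud.poses
    )


def mask_colorize_cloud(cloud: SparseCloud, mask_frames: list) -> SparseCloud:
    """Repeat colour reconstruction on the 0/255 mask sequence: the mean of
    the mask values over the track becomes the point's gray value."""
    masks = [np.asarray(m, dtype=float) * (255.0 if np.asarray(m).dtype == bool else 1.0) for m in mask_frames]
    vals, ok = _mean_track_values(cloud, masks, 1)
    if not ok.all():
        cloud = SparseCloud(
            points=cloud.points[ok],
            tracks=[t for t, k in zip(cloud.tracks, ok) if k],
            colors=None if cloud.colors is None else cloud.colors[ok],
            poses=cloud.poses,
        )
        vals = vals[ok]
    return SparseCloud(
        points=cloud.points,
        tracks=cloud.tracks,
        colors=cloud.colors,
        gray=vals[:, 0],
        poses=cloud.poses,
    )
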