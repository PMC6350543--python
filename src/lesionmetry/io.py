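"""File I/O: PNG images, JSON sidecars, ASCII PLY clouds and meshes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .mesh3d import LabeledMesh
from .phantom2d import PhantomTruth
from .recon3d import SparseCloud
from .seg2d import RoiPolygon


def save_image(path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_truth(path, truth: PhantomTruth) -> None:
    Path(path).write_text(truth.to_json())


def load_truth(path) -> PhantomTruth:
    return PhantomTruth.from_json(Path(path).read_text())


def save_roi(path, roi: RoiPolygon) -> None:
    Path(path).write_text(json.dumps(roi.to_json_dict()))


def load_roi(path) -> RoiPolygon:
    return RoiPolygon.from_json_dict(json.loads(Path(path).read_text()))


def save_cloud_ply(path, cloud: SparseCloud) -> None:
    """ASCII PLY with xyz, rgb and the reconstructed mask gray value."""
    n = len(cloud)
    colors = cloud.colors if cloud.colors is not None else np.zeros((n, 3))
    gray = cloud.gray if cloud.gray is not None else np.zeros(n)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {n}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "property float gray\nend_header\n"
        )
        for p, c, g in zip(cloud.points, colors, gray):
            fh.write(
                f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                f"{int(c[0])} {int(c[1])} {int(c[2])} {g:.3f}\n"
            )


def save_mesh_ply(path, mesh: LabeledMesh) -> None:
    """ASCII PLY triangle mesh with a per-vertex ``gray`` property."""
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(mesh.vertices)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float gray\n"
            f"element face {len(mesh.faces)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v, g in zip(mesh.vertices, mesh.gray):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {g:.3f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_mesh_ply(path) -> LabeledMesh:
    """Read a mesh written by :func:`save_mesh_ply` (ASCII, gray property)."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    n_v = n_f = 0
    for line in it:
        if line.startswith("element vertex"):
            n_v = int(line.split()[-1])
        elif line.startswith("element face"):
            n_f = int(line.split()[-1])
        elif line.strip() == "end_header":
            break
    verts, gray, faces = [], [], []
    for _ in range(n_v):
        vals = next(it).split()
        verts.append([float(x) for x in vals[:3]])
        gray.append(float(vals[3]) if len(vals) > 3 else 0.0)
    for _ in range(n_f):
        vals = next(it).split()
        faces.append([int(x) for x in vals[1:4]])
    return LabeledMesh(np.asarray(verts), np.asarray(faces, dtype=int), np.asarray(gray))


def roi_from_truth(truth: PhantomTruth, margin_px: int = 10) -> RoiPolygon:
    """Rectangular ROI around the ground-truth shape mask, emulating the
    user's rough outline around the lesion."""
    ys, xs = np.nonzero(truth.shape_mask)
    h, w = truth.shape_mask.shape
    x0 = max(0, xs.min() - margin_px)
    x1 = min(w - 1, xs.max() + margin_px)
    y0 = max(0, ys.min() - margin_px)
    y1 = min(h - 1, ys.max() + margin_px)
    return RoiPolygon(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float))
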