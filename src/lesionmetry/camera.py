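"""Pinhole camera model and rigid transforms.

World units are centimetres; image units are pixels with the convention
x right / y down, 0-based, pixel centres at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def rotation_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rotation_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rotation_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class CameraModel:
    """Ideal pinhole camera.

    ``rotation`` and ``translation`` give the world -> camera transform
    ``x_cam = R @ x_world + t``. The camera looks along +z of its own frame.
    """

    focal_length_px: float
    principal_point: np.ndarray
    image_size: tuple[int, int]  # (width, height)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.principal_point = np.asarray(self.principal_point, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.focal_length_px <= 0:
            raise ValueError("focal_length_px must be positive")
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least 64x64")

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        f = self.focal_length_px
        cx, cy = self.principal_point
        return np.array([[f, 0, cx], [0, f, cy], [0, 0, 1.0]])

    @property
    def center_world(self) -> np.ndarray:
        """Camera centre expressed in world coordinates."""
        return -self.rotation.T @ self.translation

    def project(self, points_world: np.ndarray) -> np.ndarray:
        """Project Nx3 world points to Nx2 pixel coordinates."""
        p = np.atleast_2d(np.asarray(points_world, dtype=float))
        cam = p @ self.rotation.T + self.translation
        z = cam[:, 2]
        if np.any(z <= 0):
            raise ValueError("point behind camera")
        uv = self.focal_length_px * cam[:, :2] / z[:, None] + self.principal_point
        return uv

    def pixel_rays(self) -> tuple[np.ndarray, np.ndarray]:
        """World-frame ray origin and HxWx3 unit directions for every pixel."""
        w, h = self.image_size
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        return self.rays_for_pixels(xs, ys)

    def rays_for_pixels(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cx, cy = self.principal_point
        d = np.stack(
            [
                (xs - cx) / self.focal_length_px,
                (ys - cy) / self.focal_length_px,
                np.ones_like(xs, dtype=float),
            ],
            axis=-1,
        )
        d_world = d @ self.rotation  # == d @ R, i.e. R.T applied to each row
        d_world /= np.linalg.norm(d_world, axis=-1, keepdims=True)
        return self.center_world, d_world


def look_at_camera(
    eye: np.ndarray,
    target: np.ndarray,
    focal_length_px: float,
    image_size: tuple[int, int],
    up: np.ndarray | None = None,
) -> CameraModel:
    """Camera at ``eye`` whose optical axis points at ``target``."""
    eye = np.asarray(eye, dtype=float)
    target = np.asarray(target, dtype=float)
    if up is None:
        up = np.array([0.0, 1.0, 0.0])
    fwd = target - eye
    fwd = fwd / np.linalg.norm(fwd)
    right = np.cross(up, fwd)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        right = np.cross(np.array([1.0, 0.0, 0.0]), fwd)
        nr = np.linalg.norm(right)
    right /= nr
    down = np.cross(fwd, right)
    rot = np.stack([right, down, fwd])  # rows of R: camera axes in world frame
    trans = -rot @ eye
    w, h = image_size
    return CameraModel(
        focal_length_px=focal_length_px,
        principal_point=np.array([(w - 1) / 2.0, (h - 1) / 2.0]),
        image_size=image_size,
        rotation=rot,
        translation=trans,
    )


def default_camera(
    distance_cm: float = 30.0,
    focal_length_px: float = 1500.0,
    image_size: tuple[int, int] = (720, 600),
    tilt_deg: float = 0.0,
    tilt_axis_deg: float = 0.0,
    target: np.ndarray | None = None,
) -> CameraModel:
    """Fronto-parallel camera above the world origin, optionally tilted.

    ``tilt_deg`` rotates the viewpoint away from the surface normal about an
    in-plane axis at angle ``tilt_axis_deg``, keeping the optical axis aimed
    at ``target`` (default: world origin).
    """
    if target is None:
        target = np.zeros(3)
    target = np.asarray(target, dtype=float)
    a = np.deg2rad(tilt_axis_deg)
    t = np.deg2rad(tilt_deg)
    # viewpoint on a sphere of radius distance_cm around the target
    offset = distance_cm * np.array(
        [np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), -np.cos(t)]
    )
    return look_at_camera(target + offset, target, focal_length_px, image_size)
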