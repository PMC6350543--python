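"""Synthetic 3D mesh phantoms and rendered view sequences.

A mesh phantom is a triangulated patch of a parametric support surface
(plane, cylinder, sphere, or a gently bumped plane) carrying a marked
rectangular patch whose physical area is known exactly — analytically for
developable surfaces and by the spherical-rectangle formula on the sphere
(high-order quadrature of the surface metric for the bumpy plane). A
reference segment between two mesh vertices of exactly known physical
length provides the metric scale, mirroring the manually measured
reference of the real workflow.

Rendered views ray-cast the same parametric surface with a deterministic
speckle texture so that feature-based reconstruction has something to
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .camera import CameraModel
from .phantom2d import SKIN_BASE, SHAPE_COLOR, BACKGROUND_COLOR, _texture_tile


@dataclass
class Surface3D:
    """Parametric support surface with an (approximately) isometric chart.

    kinds: ``plane`` (chart = the plane itself), ``cylinder`` (u = arc
    length around the circumference, v along the axis), ``sphere``
    (u = azimuth angle, v = polar angle from the camera-facing pole — NOT
    isometric; patch areas use the spherical formula), ``bumpy-plane``
    (plane with a sinusoidal height field).
    """

    kind: str = "plane"
    radius_cm: float | None = None
    bump_amplitude_cm: float = 0.3
    bump_wavelength_cm: float = 4.0

    def __post_init__(self):
        if self.kind in ("cylinder", "sphere") and (self.radius_cm is None or self.radius_cm <= 0):
            raise ValueError(f"{self.kind} surface needs radius_cm > 0")

    def to_world(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.kind == "plane":
            return np.stack([u, v, np.zeros_like(u)], axis=-1)
        if self.kind == "bumpy-plane":
            w = 2 * np.pi / self.bump_wavelength_cm
            z = self.bump_amplitude_cm * np.sin(w * u) * np.sin(w * v)
            return np.stack([u, v, z], axis=-1)
        if self.kind == "cylinder":
            r = self.radius_cm
            phi = u / r
            return np.stack([r * np.sin(phi), v, r * (1 - np.cos(phi))], axis=-1)
        # sphere centred at (0, 0, r); v is the polar angle from the +y pole
        # and u the azimuth about y, so (u=0, v=pi/2) is the camera-facing point
        r = self.radius_cm
        st, ct = np.sin(v), np.cos(v)
        return np.stack([r * st * np.sin(u), r * ct, r * (1 - st * np.cos(u))], axis=-1)

    def patch_area_cm2(self, u0: float, u1: float, v0: float, v1: float) -> float:
        """Exact area of the chart rectangle [u0,u1]x[v0,v1] on the surface."""
        if self.kind in ("plane", "cylinder"):
            return (u1 - u0) * (v1 - v0)
        if self.kind == "sphere":
            return self.radius_cm**2 * (u1 - u0) * (np.cos(v0) - np.cos(v1))
        # bumpy plane: integrate sqrt(1 + zx^2 + zy^2) with fine quadrature
        w = 2 * np.pi / self.bump_wavelength_cm
        a = self.bump_amplitude_cm
        n = 800
        us = np.linspace(u0, u1, n)
        vs = np.linspace(v0, v1, n)
        uu, vv = np.meshgrid(us, vs)
        zx = a * w * np.cos(w * uu) * np.sin(w * vv)
        zy = a * w * np.sin(w * uu) * np.cos(w * vv)
        integrand = np.sqrt(1 + zx**2 + zy**2)
        return float(np.trapezoid(np.trapezoid(integrand, us, axis=1), vs))


@dataclass
class MeshPhantom:
    """Triangulated surface patch with a marked region of known area."""

    vertices: np.ndarray  # (N, 3) in mesh units
    faces: np.ndarray  # (M, 3) int
    patch_vertex_flags: np.ndarray  # (N,) bool
    true_patch_area_cm2: float
    reference_vertices: tuple[int, int]
    reference_length_cm: float
    surface: Surface3D | None = None
    patch_rect: tuple[float, float, float, float] | None = None  # chart (u0, u1, v0, v1)
    texture_seed: int = 0
    mesh_units_per_cm: float = 1.0


def make_mesh_phantom(
    surface: Surface3D,
    patch_size_cm: tuple[float, float],
    resolution_cm: float = 0.05,
    padding_cm: float = 1.0,
    mesh_units_per_cm: float = 1.0,
    texture_seed: int = 0,
) -> MeshPhantom:
    """Regular-grid mesh of the surface with a centred marked patch.

    The patch boundary is aligned to fall midway between mesh rows and
    columns, so the two-white-vertex triangle rule is unbiased along a
    straight boundary. ``patch_size_cm`` is interpreted in the chart: for
    plane/cylinder these are physical cm (and the area is exact); for the
    sphere the pair is converted to angular extents about the near pole
    and the area follows the spherical-rectangle formula.
    """
    pw, ph = patch_size_cm
    if pw <= 0 or ph <= 0:
        raise ValueError("degenerate patch: zero area")
    if surface.kind == "sphere":
        r = surface.radius_cm
        # angular extents subtending the requested chart lengths at the surface
        du = pw / r
        v_c = ph / (2 * r)
        u0, u1 = -du / 2, du / 2
        v0, v1 = np.pi / 2 - v_c, np.pi / 2 + v_c  # band around the equator of the chart
        h_u = du / round(du / (resolution_cm / r))
        h_v = 2 * v_c / round(2 * v_c / (resolution_cm / r))
        pad_u = (round(padding_cm / resolution_cm) + 0.5) * h_u
        pad_v = (round(padding_cm / resolution_cm) + 0.5) * h_v
    else:
        u0, u1 = -pw / 2, pw / 2
        v0, v1 = -ph / 2, ph / 2
        h_u = pw / round(pw / resolution_cm)
        h_v = ph / round(ph / resolution_cm)
        pad_u = (round(padding_cm / h_u) + 0.5) * h_u
        pad_v = (round(padding_cm / h_v) + 0.5) * h_v
    us = np.arange(u0 - pad_u, u1 + pad_u + h_u / 2, h_u)
    vs = np.arange(v0 - pad_v, v1 + pad_v + h_v / 2, h_v)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    world = surface.to_world(uu, vv)
    nu, nv = len(us), len(vs)
    verts = world.reshape(-1, 3) * mesh_units_per_cm
    idx = np.arange(nu * nv).reshape(nu, nv)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    f2 = np.stack([idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    faces = np.concatenate([f1, f2])
    eps = 1e-9
    flags = (
        (uu > u0 + eps) & (uu < u1 - eps) & (vv > v0 + eps) & (vv < v1 - eps)
    ).reshape(-1)
    # boundary falls mid-cell: strict inequality marks exactly the interior vertices
    area = surface.patch_area_cm2(u0, u1, v0, v1)
    if area <= 0:
        raise ValueError("degenerate patch: zero area")
    # reference: two vertices on the chart v-axis extremes at mid-u (straight
    # chord; its physical length is exact from the surface map)
    i_mid = nu // 2
    ia = int(idx[i_mid, 0])
    ib = int(idx[i_mid, -1])
    ref_len = float(np.linalg.norm(verts[ia] - verts[ib])) / mesh_units_per_cm
    return MeshPhantom(
        vertices=verts,
        faces=faces,
        patch_vertex_flags=flags,
        true_patch_area_cm2=float(area),
        reference_vertices=(ia, ib),
        reference_length_cm=ref_len,
        surface=surface,
        patch_rect=(u0, u1, v0, v1),
        texture_seed=texture_seed,
        mesh_units_per_cm=mesh_units_per_cm,
    )


def _intersect_surface(surface: Surface3D, origin, dirs):
    """Ray/surface intersection in chart coordinates (iterative for bumps)."""
    from .phantom2d import _intersect_support, SupportSpec

    if surface.kind in ("plane", "bumpy-plane"):
        u, v, hit = _intersect_support(SupportSpec(kind="flat"), origin, dirs)
        if surface.kind == "bumpy-plane":
            # few fixed-point refinements of t against the height field
            dz = dirs[..., 2]
            w = 2 * np.pi / surface.bump_wavelength_cm
            for _ in range(8):
                z = surface.bump_amplitude_cm * np.sin(w * u) * np.sin(w * v)
                t = (z - origin[2]) / dz
                u = origin[0] + t * dirs[..., 0]
                v = origin[1] + t * dirs[..., 1]
        return u, v, hit
    if surface.kind == "cylinder":
        return _intersect_support(
            SupportSpec(kind="cylinder", radius_cm=surface.radius_cm), origin, dirs
        )
    # sphere centred at (0,0,r)
    r = surface.radius_cm
    center = np.array([0.0, 0.0, r])
    oc = origin - center
    b = 2 * np.einsum("...k,k->...", dirs, oc)
    c = oc @ oc - r * r
    disc = b**2 - 4 * c
    hit = disc >= 0
    t = (-b - np.sqrt(np.where(hit, disc, 0.0))) / 2
    hit &= t > 0
    p = origin + t[..., None] * dirs - center
    v = np.arccos(np.clip(p[..., 1] / r, -1, 1))
    u = np.arctan2(p[..., 0], -p[..., 2])
    return u, v, hit


def render_mesh_views(
    phantom: MeshPhantom,
    trajectory: list[CameraModel],
    supersample: int = 1,
    return_masks: bool = False,
):
    """Render the phantom's surface from each camera pose.

    The texture is a deterministic (seeded) high-contrast speckle over a
    skin-toned base, with the marked patch tinted dark; the masks (if
    requested) are the exact projected patch indicators, standing in for
    the per-frame threshold segmentation of the real workflow.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 camera poses")
    if phantom.surface is None or phantom.patch_rect is None:
        raise ValueError("phantom lacks its generating surface; cannot render")
    u0, u1, v0, v1 = phantom.patch_rect
    tile = _texture_tile(phantom.texture_seed)
    images, masks = [], []
    for cam in trajectory:
        w, h = cam.image_size
        ss = int(supersample)
        coords = (np.arange(max(w, h) * ss) + 0.5) / ss - 0.5
        xs, ys = np.meshgrid(coords[: w * ss], coords[: h * ss])
        origin, dirs = cam.rays_for_pixels(xs, ys)
        u, v, hit = _intersect_surface(phantom.surface, origin, dirs)
        if phantom.surface.kind == "sphere":
            scale = phantom.surface.radius_cm  # angles -> arc cm for texture
            tu, tv = u * scale, (v - np.pi / 2) * scale
        else:
            tu, tv = u, v
        noise = ndimage.map_coordinates(
            tile, [np.mod(tv * 8.0, tile.shape[0]), np.mod(tu * 8.0, tile.shape[1])],
            order=1, mode="grid-wrap",
        )
        fine = ndimage.map_coordinates(
            tile, [np.mod(tu * 23.0 + 71.0, tile.shape[0]), np.mod(tv * 23.0, tile.shape[1])],
            order=1, mode="grid-wrap",
        )
        in_patch = hit & (u >= u0) & (u <= u1) & (v >= v0) & (v <= v1)
        colors = np.empty(u.shape + (3,), dtype=float)
        colors[:] = SKIN_BASE * (1.0 + 0.05 * noise + 0.10 * fine)[..., None]
        colors[in_patch] = SHAPE_COLOR * (1.0 + 0.08 * noise[in_patch] + 0.10 * fine[in_patch])[..., None]
        speckle = (noise > 1.1) | (fine > 1.4)
        colors[speckle & hit] *= 0.45
        bright = (noise < -1.3) | (fine < -1.6)
        colors[bright & hit] = 250.0
        colors[~hit] = BACKGROUND_COLOR
        img = colors.reshape(h, ss, w, ss, 3).mean(axis=(1, 3))
        images.append(np.clip(img, 0, 255).astype(np.uint8))
        m = in_patch.reshape(h, ss, w, ss).mean(axis=(1, 3)) > 0.5
        if not m.any():
            raise ValueError("patch not visible in one of the views")
        masks.append(m)
    if return_masks:
        return images, masks
    return images


def orbit_trajectory(
    n_views: int,
    distance_cm: float = 25.0,
    span_deg: float = 30.0,
    focal_length_px: float = 600.0,
    image_size: tuple[int, int] = (480, 400),
    target=(0.0, 0.0, 0.0),
) -> list[CameraModel]:
    """Cameras on a small arc around the surface normal, aimed at ``target``."""
    from .camera import look_at_camera

    cams = []
    angles = np.linspace(-span_deg / 2, span_deg / 2, n_views)
    target = np.asarray(target, dtype=float)
    for a in np.deg2rad(angles):
        eye = target + distance_cm * np.array([np.sin(a), 0.0, -np.cos(a)])
        cams.append(look_at_camera(eye, target, focal_length_px, image_size))
    return cams
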