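"""Synthetic 2D wound phantoms.

A phantom is a skin-toned support surface (a flat plane or a cylinder of
known radius) carrying two printed items defined in a 2D *chart* with
coordinates (u, v) in centimetres:

* a flexible checkerboard ruler (the fiducial giving the local scale), and
* a dark geometric shape of exactly known area standing in for the lesion.

The chart is wrapped isometrically onto the support, so chart areas are
preserved, and the scene is rendered through an ideal pinhole camera with
supersampling. The returned :class:`PhantomTruth` carries the analytic
shape area, the rasterised ground-truth shape mask and the projected pixel
locations of the interior checkerboard corners, which downstream modules
use as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .camera import CameraModel, default_camera

SKIN_BASE = np.array([224.0, 172.0, 140.0])
SHAPE_COLOR = np.array([150.0, 40.0, 50.0])
BACKGROUND_COLOR = np.array([70.0, 70.0, 80.0])


@dataclass
class RulerSpec:
    """Physical geometry of the printed checkerboard ruler.

    Three checker rows produce two rows of interior corners; their spacing
    equals ``square_edge_cm`` and defines the world scale everywhere along
    the (possibly bent) ruler.
    """

    square_edge_cm: float = 0.5
    n_rows: int = 3
    n_cols: int = 16
    dark_intensity: float = 35.0
    light_intensity: float = 250.0
    margin_cm: float = 0.15

    def __post_init__(self) -> None:
        if self.square_edge_cm <= 0:
            raise ValueError("square_edge_cm must be positive")
        if self.n_rows < 3:
            raise ValueError("need at least 3 checker rows (2 corner rows)")

    @property
    def length_cm(self) -> float:
        return self.n_cols * self.square_edge_cm

    @property
    def width_cm(self) -> float:
        return self.n_rows * self.square_edge_cm


@dataclass
class ShapeSpec:
    """Planar shape of analytically known area, in chart cm coordinates."""

    kind: str  # ellipse | rectangle | polygon
    center: tuple[float, float]
    params: dict = field(default_factory=dict)

    @property
    def area_cm2(self) -> float:
        if self.kind == "ellipse":
            return float(np.pi * self.params["a"] * self.params["b"])
        if self.kind == "rectangle":
            return float(self.params["w"] * self.params["h"])
        if self.kind == "polygon":
            verts = np.asarray(self.params["vertices"], dtype=float)
            return float(_shoelace_area(verts))
        raise ValueError(f"unknown shape kind {self.kind!r}")

    def bbox(self) -> tuple[float, float, float, float]:
        """(umin, vmin, umax, vmax) of the shape in chart coordinates."""
        uc, vc = self.center
        if self.kind == "ellipse":
            a, b = self.params["a"], self.params["b"]
            return (uc - a, vc - b, uc + a, vc + b)
        if self.kind == "rectangle":
            w, h = self.params["w"], self.params["h"]
            return (uc - w / 2, vc - h / 2, uc + w / 2, vc + h / 2)
        verts = np.asarray(self.params["vertices"], dtype=float)
        return (
            uc + verts[:, 0].min(),
            vc + verts[:, 1].min(),
            uc + verts[:, 0].max(),
            vc + verts[:, 1].max(),
        )

    def contains(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        uc, vc = self.center
        du, dv = u - uc, v - vc
        if self.kind == "ellipse":
            a, b = self.params["a"], self.params["b"]
            return (du / a) ** 2 + (dv / b) ** 2 <= 1.0
        if self.kind == "rectangle":
            w, h = self.params["w"], self.params["h"]
            return (np.abs(du) <= w / 2) & (np.abs(dv) <= h / 2)
        verts = np.asarray(self.params["vertices"], dtype=float)
        return _points_in_polygon(du, dv, verts)


def regular_polygon_vertices(n_sides: int, area_cm2: float) -> np.ndarray:
    """Vertices (about the origin) of a regular n-gon with the given area."""
    r = np.sqrt(2.0 * area_cm2 / (n_sides * np.sin(2 * np.pi / n_sides)))
    ang = 2 * np.pi * np.arange(n_sides) / n_sides
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


@dataclass
class SupportSpec:
    """Support surface: flat plane z=0 or a cylinder tangent to that plane.

    The cylinder axis runs along world y; the chart u coordinate is arc
    length around the circumference and v runs along the axis, so wrapping
    is an isometry and preserves areas.
    """

    kind: str = "flat"  # flat | cylinder
    radius_cm: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "cylinder" and (self.radius_cm is None or self.radius_cm <= 0):
            raise ValueError("cylinder support needs radius_cm > 0")

    def to_world(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Map chart (u, v) cm to world 3-vectors."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.kind == "flat":
            return np.stack([u, v, np.zeros_like(u)], axis=-1)
        r = self.radius_cm
        phi = u / r
        return np.stack([r * np.sin(phi), v, r * (1.0 - np.cos(phi))], axis=-1)


@dataclass
class PhantomSceneSpec:
    support: SupportSpec
    shape: ShapeSpec
    ruler: RulerSpec = field(default_factory=RulerSpec)
    ruler_origin: tuple[float, float] = (-4.0, -4.5)  # board top-left corner (u, v)
    texture_seed: int = 0
    wound_gap_cm: float = 0.4  # clearance between ruler board and shape

    @property
    def shape_area_cm2(self) -> float:
        return self.shape.area_cm2

    def validate(self) -> None:
        if self.shape_area_cm2 <= 0:
            raise ValueError("shape area must be positive")
        su0, sv0, su1, sv1 = self.shape.bbox()
        ru0, rv0 = self.ruler_origin
        ru1 = ru0 + self.ruler.length_cm
        rv1 = rv0 + self.ruler.width_cm
        m = self.ruler.margin_cm
        if not (su0 > ru1 + m or su1 < ru0 - m or sv0 > rv1 + m or sv1 < rv0 - m):
            raise ValueError("shape and ruler overlap in the chart")
        if self.support.kind == "cylinder":
            r = self.support.radius_cm
            extent = max(abs(su0), abs(su1), abs(ru0), abs(ru1))
            if extent / r > np.pi / 2:
                raise ValueError("scene angular extent exceeds the visible half-cylinder")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom image."""

    true_area_cm2: float
    shape_mask: np.ndarray  # bool, image-sized
    ruler_corner_px: np.ndarray  # (2, n_cols-1, 2): two interior corner rows, (x, y)
    support_kind: str
    support_radius_cm: float | None
    square_edge_cm: float

    def to_json(self) -> str:
        d = {
            "true_area_cm2": self.true_area_cm2,
            "support_kind": self.support_kind,
            "support_radius_cm": self.support_radius_cm,
            "square_edge_cm": self.square_edge_cm,
            "ruler_corner_px": np.asarray(self.ruler_corner_px).tolist(),
            "shape_mask_rle": _rle_encode(self.shape_mask),
            "shape_mask_shape": list(self.shape_mask.shape),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        mask = _rle_decode(d["shape_mask_rle"], tuple(d["shape_mask_shape"]))
        return cls(
            true_area_cm2=d["true_area_cm2"],
            shape_mask=mask,
            ruler_corner_px=np.asarray(d["ruler_corner_px"], dtype=float),
            support_kind=d["support_kind"],
            support_radius_cm=d["support_radius_cm"],
            square_edge_cm=d["square_edge_cm"],
        )


def _shoelace_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _points_in_polygon(x: np.ndarray, y: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorised over points."""
    inside = np.zeros(np.shape(x), dtype=bool)
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        crosses = (y0 > y) != (y1 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (x < np.where(crosses, xi, np.inf))
    return inside


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    # run lengths, starting with a run of zeros (possibly empty)
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    if flat.size and flat[0]:
        return [0] + runs.tolist()
    return runs.tolist()


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    vals = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            vals[pos : pos + r] = True
        pos += r
        val = not val
    return vals.reshape(shape)


def _texture_tile(seed: int, n: int = 256) -> np.ndarray:
    rng = np.random.default_rng(seed)
    tile = rng.standard_normal((n, n))
    # two octaves of smoothed noise, wrap-around so sampling can tile
    t = ndimage.gaussian_filter(tile, 3.0, mode="wrap")
    t += 0.5 * ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.2, mode="wrap")
    t /= t.std()
    return t


def _chart_colors(spec: PhantomSceneSpec, u: np.ndarray, v: np.ndarray, tile: np.ndarray):
    """RGB colours (float, 0..255) and the shape indicator at chart points."""
    colors = np.empty(u.shape + (3,), dtype=float)
    noise = ndimage.map_coordinates(
        tile, [np.mod(v * 6.0, tile.shape[0]), np.mod(u * 6.0, tile.shape[1])],
        order=1, mode="grid-wrap",
    )
    colors[:] = SKIN_BASE * (1.0 + 0.035 * noise)[..., None]

    in_shape = spec.shape.contains(u, v)
    colors[in_shape] = SHAPE_COLOR * (1.0 + 0.02 * noise[in_shape, None])

    ruler = spec.ruler
    ru0, rv0 = spec.ruler_origin
    ul = u - ru0
    vl = v - rv0
    m = ruler.margin_cm
    in_paper = (
        (ul >= -m)
        & (ul <= ruler.length_cm + m)
        & (vl >= -m)
        & (vl <= ruler.width_cm + m)
    )
    in_board = (
        (ul >= 0) & (ul < ruler.length_cm) & (vl >= 0) & (vl < ruler.width_cm)
    )
    colors[in_paper] = ruler.light_intensity
    e = ruler.square_edge_cm
    i = np.floor_divide(ul, e).astype(int)
    j = np.floor_divide(vl, e).astype(int)
    dark = in_board & ((i + j) % 2 == 0)
    colors[dark] = ruler.dark_intensity
    return colors, in_shape


def _intersect_support(
    support: SupportSpec, origin: np.ndarray, dirs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chart (u, v) and a hit mask for rays against the support surface."""
    dx, dy, dz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    ox, oy, oz = origin
    if support.kind == "flat":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -oz / dz
        hit = (dz != 0) & (t > 0)
        u = ox + t * dx
        v = oy + t * dy
        return u, v, hit
    r = support.radius_cm
    # cylinder: x^2 + (z - r)^2 = r^2, axis along y
    a = dx**2 + dz**2
    b = 2 * (ox * dx + (oz - r) * dz)
    c = ox**2 + (oz - r) ** 2 - r**2
    disc = b**2 - 4 * a * c
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t = (-b - sq) / (2 * a)  # near root = front surface
    hit &= t > 0
    x = ox + t * dx
    y = oy + t * dy
    z = oz + t * dz
    phi = np.arctan2(x, r - z)
    u = r * phi
    v = y
    hit &= np.abs(phi) < np.pi / 2
    return u, v, hit


def render_phantom(
    spec: PhantomSceneSpec,
    camera: CameraModel | None = None,
    supersample: int = 2,
) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom scene; returns (HxWx3 uint8 image, PhantomTruth)."""
    spec.validate()
    if camera is None:
        camera = default_camera()
    w, h = camera.image_size
    ss = int(supersample)
    coords = (np.arange(max(w, h) * ss) + 0.5) / ss - 0.5
    xs, ys = np.meshgrid(coords[: w * ss], coords[: h * ss])
    origin, dirs = camera.rays_for_pixels(xs, ys)
    u, v, hit = _intersect_support(spec.support, origin, dirs)

    tile = _texture_tile(spec.texture_seed)
    colors, in_shape = _chart_colors(spec, np.where(hit, u, 1e6), np.where(hit, v, 1e6), tile)
    colors[~hit] = BACKGROUND_COLOR
    in_shape &= hit

    img = colors.reshape(h, ss, w, ss, 3).mean(axis=(1, 3))
    img = np.clip(img, 0, 255).astype(np.uint8)
    frac = in_shape.reshape(h, ss, w, ss).mean(axis=(1, 3))
    shape_mask = frac > 0.5
    if not shape_mask.any():
        raise ValueError("shape mask empty: shape not visible in the image")

    corners = ruler_corner_chart_points(spec)
    world = spec.support.to_world(corners[..., 0], corners[..., 1])
    corner_px = camera.project(world.reshape(-1, 3)).reshape(corners.shape)
    if (
        corner_px[..., 0].min() < 0
        or corner_px[..., 1].min() < 0
        or corner_px[..., 0].max() > w - 1
        or corner_px[..., 1].max() > h - 1
    ):
        raise ValueError("ruler projects outside the image bounds")
    sb = spec.shape.bbox()
    bbox_pts = np.array(
        [[sb[0], sb[1]], [sb[2], sb[1]], [sb[2], sb[3]], [sb[0], sb[3]]]
    )
    bb_px = camera.project(spec.support.to_world(bbox_pts[:, 0], bbox_pts[:, 1]))
    if (
        bb_px[:, 0].min() < 0
        or bb_px[:, 1].min() < 0
        or bb_px[:, 0].max() > w - 1
        or bb_px[:, 1].max() > h - 1
    ):
        raise ValueError("shape projects outside the image bounds")

    truth = PhantomTruth(
        true_area_cm2=spec.shape_area_cm2,
        shape_mask=shape_mask,
        ruler_corner_px=corner_px,
        support_kind=spec.support.kind,
        support_radius_cm=spec.support.radius_cm,
        square_edge_cm=spec.ruler.square_edge_cm,
    )
    return img, truth


def render_flat_phantom(spec: PhantomSceneSpec, camera: CameraModel | None = None, **kw):
    if spec.support.kind != "flat":
        raise ValueError("spec.support must be flat")
    return render_phantom(spec, camera, **kw)


def render_cylinder_phantom(spec: PhantomSceneSpec, camera: CameraModel | None = None, **kw):
    if spec.support.kind != "cylinder":
        raise ValueError("spec.support must be a cylinder")
    return render_phantom(spec, camera, **kw)


def ruler_corner_chart_points(spec: PhantomSceneSpec) -> np.ndarray:
    """Chart coordinates of the interior checkerboard corners.

    Returns array (2, n_cols-1, 2): two corner rows (upper then lower in v),
    one corner per interior column edge.
    """
    r = spec.ruler
    u0, v0 = spec.ruler_origin
    e = r.square_edge_cm
    us = u0 + e * np.arange(1, r.n_cols)
    out = np.empty((2, len(us), 2))
    for j, row in enumerate((1, 2)):
        out[j, :, 0] = us
        out[j, :, 1] = v0 + row * e
    return out


def centered_shape(kind: str, area_cm2: float, aspect: float = 1.0,
                   n_sides: int = 6, center_v: float | None = None) -> ShapeSpec:
    """Build a shape of exactly ``area_cm2`` placed on the wound side of the ruler.

    ``aspect`` is the height/width ratio for ellipses and rectangles.
    """
    if kind == "ellipse":
        a = float(np.sqrt(area_cm2 / (np.pi * aspect)))
        b = aspect * a
        half_h = b
        params = {"a": a, "b": b}
    elif kind == "rectangle":
        w = float(np.sqrt(area_cm2 / aspect))
        hgt = aspect * w
        half_h = hgt / 2
        params = {"w": w, "h": hgt}
    elif kind == "polygon":
        verts = regular_polygon_vertices(n_sides, area_cm2)
        half_h = float(verts[:, 1].max())
        params = {"vertices": verts}
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    if center_v is None:
        # default ruler at v0=-4.5 spans v in [-4.5, -3.0]; leave the gap below it
        center_v = -3.0 + 0.55 + half_h
    return ShapeSpec(kind=kind, center=(0.0, center_v), params=params)


def random_scene(
    rng: np.random.Generator,
    support: SupportSpec,
    area_range: tuple[float, float] = (1.13, 28.09),
    ruler: RulerSpec | None = None,
) -> PhantomSceneSpec:
    """Draw a random phantom scene in the study's area range.

    Shapes are ellipses, rectangles or regular polygons with mild aspect
    variation, constrained to fit inside the span of the rendered ruler so
    the extrapolated grid can cover the lesion.
    """
    if ruler is None:
        ruler = RulerSpec()
    area = float(rng.uniform(*area_range))
    kind = rng.choice(["ellipse", "rectangle", "polygon"])
    max_half_width = (ruler.n_cols - 2) * ruler.square_edge_cm / 2.0 - 0.3
    if kind == "polygon":
        n_sides = int(rng.integers(5, 9))
        r_needed = np.sqrt(2.0 * area / (n_sides * np.sin(2 * np.pi / n_sides)))
        if r_needed > max_half_width:
            kind = "ellipse"
    if kind == "polygon":
        shape = centered_shape("polygon", area, n_sides=n_sides)
    else:
        # clamp aspect so the width fits under the ruler span
        half_w_iso = np.sqrt(area / np.pi) if kind == "ellipse" else np.sqrt(area) / 2
        lo = max(0.55, (half_w_iso / max_half_width) ** 2)
        aspect = float(rng.uniform(lo, 1.4))
        shape = centered_shape(kind, area, aspect=aspect)
    ruler_u0 = -ruler.length_cm / 2 + float(rng.uniform(-0.2, 0.2))
    return PhantomSceneSpec(
        support=support,
        shape=shape,
        ruler=ruler,
        ruler_origin=(ruler_u0, -4.5),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )
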