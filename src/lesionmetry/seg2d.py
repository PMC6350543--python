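"""Wound/skin segmentation.

A per-pixel random-forest classifier over a small colour/texture filter
bank (RGB + LAB channels, two Gaussian scales, gradient magnitude and
Laplacian each) produces a wound-probability map; Otsu's threshold
binarises it and a user-drawn region of interest discards background and
ruler pixels. A plain intensity threshold is provided as the segmentation
used for phantom evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, rgb2lab
from skimage.draw import polygon2mask
from sklearn.ensemble import RandomForestClassifier

#: Gaussian scales (px) used by the filter bank.
FILTER_SCALES = (1.0, 2.0)


@dataclass
class FeatureStack:
    """Per-pixel feature volume (H, W, F) with a fixed, documented order."""

    features: np.ndarray
    feature_names: list[str]


@dataclass
class RoiPolygon:
    """Closed polygon in pixel coordinates, vertices as (x, y) rows."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        if _polygon_area(self.vertices) <= 0:
            raise ValueError("degenerate ROI polygon")

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        # polygon2mask expects (row, col) = (y, x)
        return polygon2mask(image_shape, self.vertices[:, ::-1])

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @classmethod
    def from_json_dict(cls, d: dict) -> "RoiPolygon":
        return cls(np.asarray(d["polygon"], dtype=float))

    def to_json_dict(self) -> dict:
        return {"polygon": self.vertices.tolist()}


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def extract_features(image: np.ndarray) -> FeatureStack:
    """Filter-bank features on RGB and LAB channels.

    For each of the 6 colour channels and each scale in
    :data:`FILTER_SCALES`: Gaussian-smoothed intensity, gradient magnitude
    and Laplacian of Gaussian, in that order. Deterministic; the order is
    part of the model contract.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    rgb = image.astype(float) / 255.0
    lab = rgb2lab(rgb)
    channels = [("rgb", i, rgb[..., i]) for i in range(3)]
    channels += [("lab", i, lab[..., i]) for i in range(3)]
    feats, names = [], []
    for space, idx, ch in channels:
        for s in FILTER_SCALES:
            g = ndimage.gaussian_filter(ch, s)
            gx = ndimage.gaussian_filter(ch, s, order=(0, 1))
            gy = ndimage.gaussian_filter(ch, s, order=(1, 0))
            feats += [g, np.hypot(gx, gy), ndimage.gaussian_laplace(ch, s)]
            base = f"{space}{idx}_s{s:g}"
            names += [f"{base}_gauss", f"{base}_gradmag", f"{base}_log"]
    return FeatureStack(np.stack(feats, axis=-1), names)


def train_classifier(
    stacks: list[FeatureStack],
    label_masks: list[np.ndarray],
    n_trees: int = 100,
    seed: int = 0,
    max_pixels_per_image: int = 100_000,
) -> RandomForestClassifier:
    """Train the wound-vs-skin random forest on labelled feature stacks.

    Pixels are subsampled per image (at most ``max_pixels_per_image``) so
    training stays desk-scale.
    """
    if len(stacks) == 0:
        raise ValueError("need at least one training image")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for stack, mask in zip(stacks, label_masks):
        f = stack.features.reshape(-1, stack.features.shape[-1])
        m = np.asarray(mask).ravel().astype(int)
        if f.shape[0] != m.shape[0]:
            raise ValueError("feature stack and label mask sizes differ")
        idx = np.arange(f.shape[0])
        if len(idx) > max_pixels_per_image:
            idx = rng.choice(idx, max_pixels_per_image, replace=False)
        xs.append(f[idx])
        ys.append(m[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; need wound and skin pixels")
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed), n_jobs=1
    )
    model.fit(x, y)
    model.n_features_expected_ = x.shape[1]
    return model


def predict_probability(model: RandomForestClassifier, image: np.ndarray) -> np.ndarray:
    """Per-pixel wound probability map in [0, 1]."""
    stack = extract_features(image)
    f = stack.features.reshape(-1, stack.features.shape[-1])
    if f.shape[1] != getattr(model, "n_features_expected_", f.shape[1]):
        raise ValueError("feature dimension does not match the trained model")
    wound_col = list(model.classes_).index(1)
    p = model.predict_proba(f)[:, wound_col]
    return p.reshape(image.shape[:2])


def otsu_binarize(prob: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Binarise a probability map at the threshold maximising between-class
    variance of its histogram (Otsu's criterion)."""
    prob = np.asarray(prob, dtype=float)
    if prob.max() == prob.min():
        raise ValueError("constant probability map: no threshold exists")
    t = otsu_threshold(prob, n_bins)
    return prob > t


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of an array, computed on an ``n_bins`` histogram."""
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    hist, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_all * cum_w - cum_m) ** 2 / (cum_w * (total - cum_w))
    between[~np.isfinite(between)] = -1.0
    k = int(np.argmax(between))
    return float(centers[k])


def apply_roi(mask: np.ndarray, roi: RoiPolygon) -> np.ndarray:
    """Zero out mask pixels outside the ROI polygon; idempotent."""
    mask = np.asarray(mask, dtype=bool)
    return mask & roi.mask(mask.shape)


def threshold_segment(
    image: np.ndarray, threshold: float, invert: bool = False
) -> np.ndarray:
    """Global luminance threshold: mask = gray >= threshold (<= if invert).

    This is the segmentation used for phantom evaluation, where the operator
    picks one suitable threshold per image; dark lesions on light skin are
    segmented with ``invert=True``.
    """
    img = np.asarray(image)
    gray = rgb2gray(img.astype(float) / 255.0) * 255.0 if img.ndim == 3 else img.astype(float)
    return gray <= threshold if invert else gray >= threshold
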