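"""Batch evaluation of phantom measurements.

Errors follow the study convention: unsigned absolute error
|A_meas - A_true| in cm^2 and relative error 100*|A_meas - A_true|/A_true
in percent, summarised as mean +/- standard deviation per support class.
Signed errors are kept for diagnostics, and images whose grid degenerates
(converging columns, lesion off the grid) are excluded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid2d import GridError, measure_area_2d
from .io import load_image, load_roi, load_truth, roi_from_truth
from .ruler import RulerDetectionError


@dataclass
class ImageResult:
    name: str
    true_area_cm2: float
    measured_area_cm2: float | None
    support_kind: str
    excluded_reason: str | None = None

    @property
    def abs_error_cm2(self) -> float | None:
        if self.measured_area_cm2 is None:
            return None
        return abs(self.measured_area_cm2 - self.true_area_cm2)

    @property
    def signed_error_cm2(self) -> float | None:
        if self.measured_area_cm2 is None:
            return None
        return self.measured_area_cm2 - self.true_area_cm2

    @property
    def rel_error_pct(self) -> float | None:
        if self.measured_area_cm2 is None:
            return None
        return 100.0 * self.abs_error_cm2 / self.true_area_cm2


@dataclass
class BatchSummary:
    results: list[ImageResult] = field(default_factory=list)

    @property
    def included(self) -> list[ImageResult]:
        return [r for r in self.results if r.excluded_reason is None]

    @property
    def excluded(self) -> list[ImageResult]:
        return [r for r in self.results if r.excluded_reason is not None]

    def stats(self, support_kind: str | None = None) -> dict:
        rows = self.included
        if support_kind is not None:
            rows = [r for r in rows if r.support_kind == support_kind]
        if not rows:
            return {"n": 0}
        abs_e = np.array([r.abs_error_cm2 for r in rows])
        rel_e = np.array([r.rel_error_pct for r in rows])
        return {
            "n": len(rows),
            "abs_error_mean_cm2": float(abs_e.mean()),
            "abs_error_sd_cm2": float(abs_e.std(ddof=1)) if len(rows) > 1 else 0.0,
            "rel_error_mean_pct": float(rel_e.mean()),
            "rel_error_sd_pct": float(rel_e.std(ddof=1)) if len(rows) > 1 else 0.0,
        }

    def to_dict(self) -> dict:
        kinds = sorted({r.support_kind for r in self.included})
        return {
            "per_image": [
                {
                    "name": r.name,
                    "true_cm2": r.true_area_cm2,
                    "measured_cm2": r.measured_area_cm2,
                    "abs_error_cm2": r.abs_error_cm2,
                    "signed_error_cm2": r.signed_error_cm2,
                    "rel_error_pct": r.rel_error_pct,
                    "support": r.support_kind,
                    "excluded": r.excluded_reason,
                }
                for r in self.results
            ],
            "summary": {"all": self.stats(), **{k: self.stats(k) for k in kinds}},
            "n_excluded": len(self.excluded),
        }


def measure_phantom_image(
    image, truth, roi=None, threshold: float = 120.0, model=None
):
    """Measure one phantom image; ROI defaults to a box around the truth mask."""
    if roi is None:
        roi = roi_from_truth(truth)
    return measure_area_2d(
        image,
        roi,
        truth.square_edge_cm,
        model=model,
        threshold=None if model is not None else threshold,
        invert=True,
    )


def evaluate_batch(dataset_dir, threshold: float = 120.0, model=None) -> BatchSummary:
    """Measure every ``*.png`` with a ``*.truth.json`` sidecar in a directory."""
    dataset_dir = Path(dataset_dir)
    images = sorted(p for p in dataset_dir.glob("*.png") if not p.stem.endswith("mask"))
    if not images:
        raise FileNotFoundError(f"no phantom images in {dataset_dir}")
    summary = BatchSummary()
    for img_path in images:
        truth_path = img_path.with_suffix("").with_suffix(".truth.json")
        if not truth_path.exists():
            truth_path = Path(str(img_path)[: -len(".png")] + ".truth.json")
        if not truth_path.exists():
            continue
        truth = load_truth(truth_path)
        image = load_image(img_path)
        roi_path = Path(str(img_path)[: -len(".png")] + ".roi.json")
        roi = load_roi(roi_path) if roi_path.exists() else None
        kind = truth.support_kind + (
            "" if truth.support_radius_cm is None else f"_r{truth.support_radius_cm:g}"
        )
        try:
            res = measure_phantom_image(image, truth, roi=roi, threshold=threshold, model=model)
            reason = None
            for w in res.warnings:
                if "converging" in w or "outside the grid" in w:
                    reason = w
                    break
            summary.results.append(
                ImageResult(
                    name=img_path.name,
                    true_area_cm2=truth.true_area_cm2,
                    measured_area_cm2=None if reason else res.total_area_cm2,
                    support_kind=kind,
                    excluded_reason=reason,
                )
            )
        except (GridError, RulerDetectionError) as exc:
            summary.results.append(
                ImageResult(
                    name=img_path.name,
                    true_area_cm2=truth.true_area_cm2,
                    measured_area_cm2=None,
                    support_kind=kind,
                    excluded_reason=str(exc),
                )
            )
    if not summary.results:
        raise FileNotFoundError(f"no (image, truth) pairs found in {dataset_dir}")
    return summary
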