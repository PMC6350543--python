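"""Reproducible phantom study batches.

These functions re-run the package's validation studies from scratch:
randomised 2D phantom batches (flat and cylindrical supports, optional
camera tilt) measured with the full ruler pipeline, and the five-mesh 3D
batch measured from the labelled-mesh stage onward. Each batch derives its
random stream from a base seed combined with a fixed per-study stream id,
so independent studies stay decoupled while the whole run is reproducible
from one integer.
"""

from __future__ import annotations

import numpy as np

from .camera import default_camera
from .grid2d import measure_area_2d
from .io import roi_from_truth
from .mesh3d import LabeledMesh, ReferenceSegment, calibrate_scale, measure_area_3d, smooth_and_fill
from .phantom2d import SupportSpec, random_scene, render_phantom
from .phantom3d import Surface3D, make_mesh_phantom

#: the five mesh-phantom study cases: (cylinder radius cm, patch area cm2)
MESH_STUDY_CASES = [(19.5, 10.8), (19.5, 16.2), (19.5, 21.6), (8.5, 10.8), (8.5, 16.2)]

SUPPORT_FLAT = SupportSpec(kind="flat")
SUPPORT_LOW = SupportSpec(kind="cylinder", radius_cm=19.5)
SUPPORT_HIGH = SupportSpec(kind="cylinder", radius_cm=8.5)


def batch_2d(
    base_seed: int,
    stream: int,
    supports: list[SupportSpec],
    n: int,
    tilt_max_deg: float = 0.0,
    threshold: float = 120.0,
) -> list[dict]:
    """Render and measure ``n`` random phantoms, cycling through ``supports``.

    Returns one record per phantom with the true and measured area and the
    unsigned absolute (cm^2) and relative (%) errors.
    """
    rng = np.random.default_rng([base_seed, stream])
    records = []
    for i in range(n):
        support = supports[i % len(supports)]
        scene = random_scene(rng, support)
        cam = default_camera(
            tilt_deg=float(rng.uniform(0.0, tilt_max_deg)),
            tilt_axis_deg=float(rng.uniform(0.0, 360.0)),
        )
        image, truth = render_phantom(scene, cam)
        res = measure_area_2d(image, roi_from_truth(truth), truth.square_edge_cm,
                              threshold=threshold)
        true = truth.true_area_cm2
        records.append(
            {
                "support": support.kind
                + ("" if support.radius_cm is None else f"_r{support.radius_cm:g}"),
                "true_cm2": true,
                "measured_cm2": res.total_area_cm2,
                "abs_error_cm2": abs(res.total_area_cm2 - true),
                "rel_error_pct": 100.0 * abs(res.total_area_cm2 - true) / true,
            }
        )
    return records


def mesh_batch_3d(base_seed: int, stream: int = 3, noise_sigma_cm: float = 0.02) -> list[dict]:
    """Measure the five mesh-phantom study cases from the labelled mesh on.

    Each phantom's vertices are perturbed by Gaussian noise of
    ``noise_sigma_cm`` (0.2 mm by default), smoothed, scaled via its
    reference segment and measured with the two-white-vertex triangle rule.
    """
    rng = np.random.default_rng([base_seed, stream])
    records = []
    for radius, area in MESH_STUDY_CASES:
        side = float(np.sqrt(area))
        ph = make_mesh_phantom(Surface3D(kind="cylinder", radius_cm=radius), (side, side))
        noisy = ph.vertices + rng.normal(0.0, noise_sigma_cm, ph.vertices.shape)
        mesh = LabeledMesh(noisy, ph.faces, ph.patch_vertex_flags * 255.0)
        mesh = smooth_and_fill(mesh)
        ia, ib = ph.reference_vertices
        mesh = calibrate_scale(
            mesh, ReferenceSegment(mesh.vertices[ia], mesh.vertices[ib], ph.reference_length_cm)
        )
        res = measure_area_3d(mesh)
        records.append(
            {
                "radius_cm": radius,
                "true_cm2": area,
                "measured_cm2": res.total_area_cm2,
                "abs_error_cm2": abs(res.total_area_cm2 - area),
                "rel_error_pct": 100.0 * abs(res.total_area_cm2 - area) / area,
            }
        )
    return records


def mean_rel_error(records: list[dict]) -> float:
    return float(np.mean([r["rel_error_pct"] for r in records]))
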