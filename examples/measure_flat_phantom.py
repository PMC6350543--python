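"""Measure a flat synthetic phantom with the 2D ruler pipeline.

Renders a photograph of an elliptical test lesion of exactly known area
next to a checkerboard paper ruler, then runs segmentation, ruler
detection, grid extrapolation and the per-square area rule.
"""

from lesionmetry.camera import default_camera
from lesionmetry.grid2d import measure_area_2d
from lesionmetry.io import roi_from_truth
from lesionmetry.phantom2d import PhantomSceneSpec, SupportSpec, centered_shape, render_phantom

spec = PhantomSceneSpec(
    support=SupportSpec(kind="flat"),
    shape=centered_shape("ellipse", 14.137, aspect=0.8),  # pi * 2.37 * 1.90 cm
    texture_seed=1,
)
image, truth = render_phantom(spec, default_camera())
roi = roi_from_truth(truth)  # the user's rough outline around the lesion

result = measure_area_2d(image, roi, square_edge_cm=0.5, threshold=120.0)

err = abs(result.total_area_cm2 - truth.true_area_cm2)
print(f"true area      : {truth.true_area_cm2:.3f} cm^2")
print(f"measured area  : {result.total_area_cm2:.3f} cm^2")
print(f"absolute error : {err:.3f} cm^2")
print(f"relative error : {100 * err / truth.true_area_cm2:.2f} %")
print(f"grid squares   : {len(result.per_square)} contributed wound pixels")
# The measured area is the sum over unwarped grid squares of
# (wound pixels / total pixels) * (0.5 cm)^2.
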