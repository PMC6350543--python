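# Methods

## Scope and model

The package measures the surface area of a skin lesion from photographs
under two acquisition models.

The **2D model** assumes a single photo containing the lesion and a
flexible printed checkerboard ruler lying next to it, conforming to the
skin. The skin patch is treated as locally developable: the ruler, bending
with the surface, samples the local image scale along one direction, and
the scale transverse to the ruler is taken from the spacing of its two
interior corner rows. Under these assumptions each extrapolated grid cell
corresponds to one physical square of the ruler, and the pixel-fraction
rule A_w = (N_w/N)·e² (e = square edge in cm) converts per-cell wound
coverage to physical area. The model breaks down when the camera is far
from perpendicular (the grid columns then converge or diverge — flagged as
warnings and treated as exclusions in batch evaluation) and when the
surface bends along the extrapolation direction, which the single view
cannot observe.

The **3D model** assumes a short video orbit of the lesion with a
reference length of known size. The reconstruction is sparse
structure-from-motion up to a global similarity; the metric scale enters
exclusively through the reference segment. The lesion label lives on the
mesh as a per-vertex gray value obtained by averaging the per-frame
segmentation masks along each point's observation track, and a triangle
counts toward the area iff at least two of its vertices are white
(gray > 127).

## Pipeline parameters

| parameter | default | role |
|---|---|---|
| ruler square edge | 0.5 cm | physical scale; configurable, never hard-coded downstream |
| checker rows | 3 | gives two interior corner rows; fixed by the ruler design |
| structure-tensor gradient σ | 1 px | derivative scale |
| structure-tensor window σ | 3 px | outer-product averaging; about an eighth of the rendered square edge, small enough that neighbouring corners (≳ 12 px apart) stay separated |
| corner quality | 0.15 of max λ₂ | candidate threshold |
| corner classification window | 0.6 × median corner spacing | diagonal-mean comparison; similar within 15 %, different beyond 25 % of the intensity range |
| edge-line circle radius | 0.4 × smallest corner spacing | PCA support for checker-edge lines |
| grid extent | ROI bbox + 1 row, max 50 rows | extrapolation away from the ruler, toward the ROI only |
| unwarp resolution | max(16, median quad edge px) | samples at output-cell centres so adjacent quads tile exactly |
| RF segmenter | 100 trees, seeded, ≤10⁵ px/image | wound vs skin over 36 features (RGB+LAB × 2 Gaussian scales × {smoothed, gradient magnitude, LoG}) |
| Otsu | 256-bin histogram | probability-map binarisation |
| SfM RANSAC | 1.5 px epipolar residual, 1000 trials, seeded | essential-matrix verification in normalised coordinates |
| isolation filter | r = 2 × median NN distance, ≥ 5 neighbours | sparse-cloud outlier removal |
| Laplacian smoothing | λ = 0.5, 10 iterations, boundary fixed | mesh noise-area removal |
| hole rule | boundary loops < 75 % of longest | interior holes, fan-filled from the centroid |
| gray threshold | 127 | white-vertex rule for the triangle sum |

Numerical conventions: pixels are 0-based, x right / y down, centres at
integers; world units are centimetres. Corner and crossing positions are
refined to sub-pixel by parabolic fits. 2×2 eigenproblems (structure
tensor, PCA lines) are solved in closed form. Quadrilateral ownership of a
pixel is resolved to the nearest quad centre so bent grids never double
count. Degenerate inputs (constant probability maps, collinear corner
rows, zero-length references, unscaled meshes) raise typed errors rather
than returning numbers.

## The synthetic phantom generator

Physical phantom studies with known-area paper shapes are the only way to
validate photographic planimetry, and this package replaces them with
rendered equivalents. A 2D phantom scene is defined in a chart (cm) that
is wrapped isometrically onto a flat plane or a cylinder tangent to it
(radii 19.5 cm and 8.5 cm serve as the low/high-curvature study supports;
wrapping preserves areas, so the analytic shape area is exact ground
truth). The scene carries a skin-toned two-octave noise texture attached
to the surface, a dark lesion shape (ellipse, rectangle, or regular
polygon; study draws span 1.13–28.09 cm²), and the rendered ruler. Scenes
are ray-cast through an ideal pinhole camera (default 30 cm distance,
f = 1500 px, 720×600 px, ≈25 px per square) with 2×2 supersampling;
a tilt parameter moves the viewpoint off the surface normal while keeping
aim. Ground truth includes the rasterised shape mask and the projected
interior-corner lattice, which the detector tests use as an oracle.

3D mesh phantoms are regular-grid triangulations (0.5 mm spacing) of a
parametric surface with a centred marked patch. Patch boundaries are
aligned to fall midway between mesh rows, which makes the two-white-vertex
triangle rule unbiased along straight boundaries. Rendered view sequences
use a deterministic speckle texture (two octaves, dark and bright dots) so
SIFT has features to track, and the exact projected patch indicator
stands in for the per-frame threshold segmentation of the real workflow.

What the phantoms deliberately do not emulate: specular reflections, lens
distortion, motion blur, colour casts, ambiguous wound boundaries, or
segmentation disagreement between observers. Passing phantom studies
therefore demonstrates the correctness and numerical behaviour of the
measurement chain under ideal acquisition — not clinical segmentation
accuracy, which would require annotated clinical images.

## Study conditions

The validation batches (tests and `scripts/acceptance.py`) use: 20 flat
fronto-parallel phantoms; 30 phantoms cycling flat/19.5 cm/8.5 cm supports
with camera tilt drawn uniformly from [0°, 5°]; 10 phantoms per cylinder
support with the same tilt; threshold segmentation at gray 120 with a
bounding-box ROI 10 px around the truth mask (emulating the user's rough
outline). The five 3D study phantoms are cylinder patches of 10.8, 16.2
and 21.6 cm² (r = 19.5 cm) and 10.8 and 16.2 cm² (r = 8.5 cm) with
0.2 mm Gaussian vertex noise, measured from the labelled-mesh stage
(smooth → fill → reference scale → triangle sum). Observed errors are
well under the corresponding physical-study statistics (means ≈ 0.2–1.1 %
relative in 2D; ≤ 2.3 % relative, ≤ 0.4 cm² absolute in 3D), as expected
for ideal synthetic acquisition.

## Design choices where the design was open

- **Filter bank.** No canonical composition exists for wound/skin pixel
  classification, so the bank is a standard
  texture set: per RGB and LAB channel, Gaussian smoothing, gradient
  magnitude and Laplacian of Gaussian at σ ∈ {1, 2} px, in a fixed
  documented order.
- **Distance-transform ridge.** "Local maxima of the DT" is ambiguous
  (1D vs 2D maxima); implemented as maxima along the direction transverse
  to the corner set's principal axis, sub-pixel refined, then smoothed by
  a spline and extended by ¾ corner spacing past the outermost corners so
  the outermost checker edges still produce crossings.
- **Edge-crossing detector.** Implemented as extrema of the smoothed
  intensity derivative along the centerline above a contrast threshold;
  crossings that fail to find corners on both sides (e.g. the board's
  outer ends) are dropped with a warning.
- **Grid side.** Rows extend only toward the ROI; the ruler is assumed
  placed beside the lesion, and pair orientation is auto-corrected by
  majority vote against the ROI centroid.
- **2.5D Delaunay.** Wound surfaces are height fields over a base plane,
  so points are triangulated in their best-fit plane; a full 3D
  reconstruction of topology would add nothing here.
- **SfM backend.** Incremental two-view initialisation (best
  inliers × parallax among consecutive pairs), pose chaining by
  reprojection refinement, then three rounds of alternating full-track
  retriangulation and per-pose refinement — this removes most chain drift
  without a joint bundle adjustment. Landmarks observed at the same pixel
  are merged (SIFT emits one keypoint per orientation). Reconstruction
  requires intrinsics; for real video a focal of 0.9 × image width is a
  serviceable default when EXIF is absent.
- **Smoothing before measuring.** The triangle sum runs on the smoothed,
  hole-filled mesh: raw reconstruction noise otherwise inflates the area
  (roughness adds spurious surface).

## Known limitations

- The 2D method cannot detect, only flag, strongly non-perpendicular
  views; tilt beyond a few degrees biases the extrapolated grid.
- End-to-end 3D measurement from a sparse feature cloud under-covers the
  patch by a boundary band of roughly half the feature spacing (the
  two-white-vertex rule needs vertices on both sides of the boundary);
  with the default speckle density this is about 10 % on a 10-view orbit.
  Denser texture or frames reduce it; the labelled-mesh studies, which
  isolate the measurement stages, are accurate to ≈ 2 %.
- The one-pass isolation filter is not idempotent (removing points lowers
  survivors' neighbour counts); this matches its definition as a single
  neighbour-count pass.
- Reflections on the ruler can defeat corner classification; the real
  workflow fixes these manually, and the library surfaces them as dropped
  pairs rather than attempting inpainting.
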