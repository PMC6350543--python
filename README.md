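# lesionmetry

Photographic surface-area measurement of skin lesions, for wound
documentation and treatment monitoring where planimetry hardware (laser
scanners, structured light) is unavailable — home care, telemedicine,
desk-scale studies.

Two measurement routes are implemented:

**2D, single photo with a flexible paper ruler.** A checkerboard strip of
known square size lies next to the lesion and follows the skin curvature.
Detection runs on structure-tensor eigenvalue maps (one large eigenvalue =
edge, two = corner): corner candidates are classified as checkerboard
corners by comparing diagonal window intensities, the ruler's medial
centerline is the ridge of the distance transform of the corner points,
and each intensity transition along that curve is refined by PCA over
high-eigenvalue pixels into a checker-edge line. Walking each edge line to
the two corner rows yields correspondence pairs (p1, p2) with local scale
step d = ‖p1 − p2‖₂. Extending every pair's line equidistantly with step d
builds a grid whose cells each represent one physical square; each
quadrilateral is unwarped by a homography to a square and the wound area
inside it is

    A_w = (N_w / N) · (square edge)² ,

summed over all grid squares (N = pixels in the unwarped square, N_w =
wound pixels). The method needs no prior knowledge of how many squares are
visible. Wound pixels come either from a random-forest wound/skin
classifier over an RGB+LAB filter bank (Otsu-binarised probability map,
masked by a user-drawn ROI) or from a plain intensity threshold.

**3D, image sequence.** Sparse structure-from-motion (SIFT features,
essential-matrix RANSAC, incremental pose chaining with track-based
retriangulation) produces a point cloud; isolated points are dropped,
per-point colour and mask values are the means over the observation
tracks, a 2.5D Delaunay mesh is smoothed (Laplacian, boundary fixed) and
hole-filled, the metric scale is calibrated from a reference segment of
known length, and the lesion area is the sum of triangle areas with at
least two vertices whose reconstructed mask gray value exceeds 127.

Because clinical images with known ground truth are essentially
unobtainable, the package ships a first-class synthetic phantom generator:
2D scenes (flat and cylindrical supports, rendered ruler, shapes of
analytically known area, pinhole camera with tilt) and 3D mesh phantoms
with marked patches of exact geodesic area — the basis of the whole test
suite.

## Worked example

```sh
python examples/measure_flat_phantom.py
```

```
true area      : 14.137 cm^2
measured area  : 14.134 cm^2
absolute error : 0.003 cm^2
relative error : 0.02 %
grid squares   : 72 contributed wound pixels
```

A 14.137 cm² ellipse (semi-axes 2.37 × 1.90 cm) is rendered next to a
0.5 cm-square ruler, segmented by thresholding, and measured through the
detected grid: 72 unwarped squares contribute wound pixels, and their
pixel-fraction sum reproduces the analytic area to 0.02 %. The other examples
cover ruler detection on a strongly bent support
(`ruler_detection_stages.py`), the mesh-based 3D measurement
(`mesh_phantom_area.py`), sparse reconstruction (`sfm_reconstruction.py`)
and random-forest segmentation (`train_segmenter.py`).

The same functionality is scriptable from the shell:

```sh
lesionmetry synth 2d --out phantoms/ --seed 5 --count 10
lesionmetry measure2d --image photo.png --roi roi.json --square-cm 0.5 --threshold 120
lesionmetry eval --dataset phantoms/
```

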