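# Methods

`podmetrics` measures the number, length, width and two-dimensional
area of seed pods (siliques of *Brassica napus* and similar fruits)
from RGB photographs of detached pods spread on a dark background, with
a coin of known diameter placed at the far-left edge of the frame as
the metric reference.  This note records the model behind each step,
the tunable parameters and their defaults, the numerical conventions,
and the known limitations.

## Segmentation model

Scenes are assumed to be high-contrast: near-black velvet, matte pods,
a bright metal coin.  Foreground recovery is classical:

1. grayscale conversion with BT.601 luma weights (0.299, 0.587, 0.114);
2. Gaussian blur (reflect padding, kernel truncated at 4 sigma).  The
   default sigma is 1.5 px at the reference resolution of 2400 x 1600
   and scales with the linear image resolution, so that smoothing is a
   property of the scene rather than of the sensor; an explicit
   `blur_sigma` is taken as absolute pixels;
3. global Otsu thresholding (a fixed threshold is available as an
   override), foreground = intensity strictly above the threshold;
4. removal of 8-connected components below a minimum pixel area
   (default 150 px^2 at 2400 x 1600, scaled by relative image area), to
   absorb dust and lint on the cloth;
5. per-component threshold refinement (`refine_threshold`, default on).
   With both dull pods and a shiny coin in frame the global foreground
   class is bimodal, so Otsu's threshold settles above the
   pod/background midpoint and shaves a sigma-dependent fraction of a
   pixel off every pod edge — a bias that matters for pods only 10 px
   wide and that varies with resolution.  Each component is therefore
   re-binarized inside its padded bounding box at the midpoint between
   the component's median intensity and the median of the nearby
   background, which centres the boundary on the physical edge at any
   blur level.

Connectivity is 8-connected foreground / 4-connected background;
coordinates are (x = column, y = row), origin at the top-left pixel
center.

## Contours and the boundary convention

Each component's outer boundary is traced with marching squares at
level 0.5 (holes are ignored).  Vertices sit on pixel-edge midpoints
("mid-crack"), so the polygon's shoelace area equals the component's
pixel count — a filled 10 x 10 square measures 100 px^2, and area
estimates are unbiased at any resolution.  The raw mid-crack chain
zigzags along oblique edges and would overestimate their Euclidean
length by up to ~8%, so the closed vertex chain is smoothed with a
circular moving average (default window 5 vertices, roughly 5 px of
arc).  The window trades staircase noise against corner rounding: a
smoothed right-angle corner loses ~1 px^2 of area and ~1 px of
perimeter, negligible for objects tens of pixels across.  Window 1
disables smoothing.

Invariant checks maintained by tests: shoelace area is preserved under
translation and cyclic rotation of the vertex list, scales as s^2 under
coordinate scaling (perimeter as s), and every traced contour respects
the isoperimetric bound area <= perimeter^2 / (4 pi).

## Coin identification and calibration

The coin is the leftmost contour that is round (circularity
4 pi A / P^2 >= 0.8) and at least 500 px^2.  Exactly one coin per image
is assumed; no qualifying contour raises an error that carries the best
circularity seen, which distinguishes "no coin" from "threshold too
strict".  Multi-coin scenes resolve to the smallest centroid x.

The coin's pixel diameter is the mean of the two midpoint-to-midpoint
distances (top-bottom, left-right) of its minimum-area rotated bounding
rectangle; the mean of the two axes makes the estimate insensitive to
the rectangle's orientation and to slight ellipticity from perspective.
Box corners are ordered clockwise on screen starting from the topmost
(tie: leftmost) corner and labelled top-left, top-right, bottom-right,
bottom-left.

Two conversion factors follow:

    diameter_ratio = coin_diameter_true / coin_diameter_pixel    [mm/px]
    area_ratio     = coin_area_true     / coin_area_pixel        [mm2/px2]

with `coin_diameter_true` = 25 mm by default (a one-RMB coin) and
`coin_area_true` = pi (d/2)^2.  For a perfectly circular coin
`area_ratio` equals `diameter_ratio` squared; on rasterized disks the
two agree within 2%, and keeping both lets lengths and areas calibrate
independently.

## Pod morphometry

For each non-coin contour:

* **length** = contour perimeter / 2 (half-perimeter).  For a straight
  rectangular pod of true length L and width w this returns L + w — a
  deliberate, documented overestimate of about one pod width (~5% for
  typical pods).  The bias grows with curvature: half the perimeter of
  a constant-width tube around a curved centerline exceeds the
  centerline length by more than one width.
* **width** = contour area / length.  For the same rectangle this is
  L w / (L + w), slightly under the true width.  The isoperimetric
  inequality guarantees width <= length / pi for any simple contour,
  so the two traits never cross.
* **area** = shoelace area of the contour.

Physical values are the pixel values times `diameter_ratio` (lengths)
or `area_ratio` (areas).  Pods are numbered left to right by contour
centroid x (ties by y).  Summaries report mean/median/min/max on raw
values and the mode on values rounded to a configurable number of
decimals (default 1, ties resolved to the smallest value).  Two
measurement series (e.g. machine vs manual calipers) are compared by
ordinary least squares with the coefficient of determination.

## Synthetic scenes

Real measurement photographs are not redistributable, so tests and
examples run on rendered look-alikes: background intensity 15/255,
pods at 150, coin at 230 (values chosen to keep Otsu separation robust
while far from saturation), optional additive Gaussian sensor noise.
Object silhouettes are exact vector shapes — the coin a 256-gon disk,
straight pods flat-capped rectangles, bent pods round-capped
constant-half-width tubes around a quadratic Bezier arc rescaled to the
nominal centerline length — rasterized by pixel-center containment, so
ground-truth masks, lengths, widths and areas are analytic.  Sampled
pod lengths span 4.7-15.1 cm and widths 0.2-0.5 cm, the range reported
for manually measured rapeseed pods; placements are rejection-sampled
to be pairwise disjoint with the coin in the left quarter of the frame.
Rendering is deterministic: identical specs (including the seed) give
byte-identical images.

What the generator does **not** emulate: texture, shadows, specular
highlights on the coin, touching or overlapping pods, stalk debris,
uneven illumination, lens distortion.  Passing tests therefore
demonstrate the correctness of the geometry, calibration and metric
machinery — not detection robustness on difficult field imagery, where
an instance-segmentation model supplies the masks instead of
thresholding (`load_predictions` accepts any detector's COCO results
JSON).

## Evaluation metrics

Ground truth vs predicted masks are scored with COCO conventions:
greedy score-ordered one-to-one matching (ties to the lower
ground-truth index), 101-point interpolated average precision, AP
averaged over IoU 0.50-0.95 in steps of 0.05, and size strata at 32^2
and 96^2 px with ignore semantics (out-of-stratum ground truth is
ignored; detections matched to ignored ground truth, or unmatched with
out-of-stratum area, are dropped from the ranking).  A stratum with no
ground truth reports a missing value, printed as "Nan" in the console
table.  Set-level precision and recall are computed at IoU 0.5, with
0/0 defined as 0.  Box-level metrics reuse the same machinery on
filled bounding boxes.  The implementation is verified against an
exhaustive brute-force PR-curve evaluator on randomized small cases.

## Dataset tooling

Labelme polygon JSON is read (non-polygon shapes skipped with a
warning, vertices clipped to image bounds) and converted to COCO
instances JSON with deterministic ids (images sorted by file name),
shoelace areas, tight bounding boxes and iscrowd = 0; the category
scheme defaults to a single "pod" class.  COCO RLE masks (uncompressed
counts and the compressed string encoding) are decoded and encoded
natively.  Augmentations keep image and polygons in lockstep through
the same affine map; quarter-turn rotations and flips use exact index
permutations so their identities hold bit-for-bit, arbitrary rotations
expand the canvas to avoid cropping corners.  Photometric operations
(Gaussian noise, blur, cutout rectangles, brightness/contrast/
saturation jitter) leave polygons untouched and draw all randomness
from the spec seed.  Crops drop instances retaining less than 20% of
their area.  Mosaic composes four annotated images on a 2 x 2 canvas
with polygon offsets equal to the tile origins.  Train/validation
splits are image-level with a seeded shuffle (default 9:1).

## Numerical choices and degenerate inputs

* Thresholding uses strict `>`; an image uniformly at the threshold is
  all background.
* `mask_iou` of two empty masks is 0; precision and recall with empty
  denominators are 0.
* Contours need >= 3 vertices; degenerate (zero-length) contours raise
  rather than return infinite widths.
* Box-corner ordering rejects collinear quadruples.
* The measurement pipeline treats a coinless image as a per-image
  failure (batch processing continues; exit code 1), and a scene with a
  coin but no pods as an empty, successful result.
* All stochastic components (scene sampling, noise, augmentation,
  splits) take explicit integer seeds; nothing reads global RNG state.

## Problem sizes used in checks

Property checks run on scenes of 1200 x 800 px at 0.2 mm/px (scale
invariance compares against 2400 x 1600 at 0.1 mm/px) with 3-5 pods per
scene, 20-scene recovery sweeps, 200 randomized blobs for the
isoperimetric bound, 200 random toy instance sets for the AP oracle,
and an 18-image batch for determinism — sizes at which the geometry
errors are dominated by the estimators themselves rather than by
sampling noise.

## Known limitations

* Half-perimeter length systematically overestimates true centerline
  length by about one width, and more for strongly curved pods; the
  bias is documented rather than corrected (no curvature-corrected
  centerline is attempted).
* Width is a contour-averaged quantity, not a profile; beak and stalk
  remnants included in the detected contour inflate length and dilute
  width.
* Thresholding assumes a dark, uniform background; color-based
  segmentation and illumination correction are out of scope.
* The coin must be fully visible, unoccluded and the leftmost round
  object; denominations are not recognized automatically.
* No perspective or lens-distortion correction: the coin and pods are
  assumed to lie in the same image plane.
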