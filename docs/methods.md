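# Methods

This note documents the models, parameter choices and numerical decisions
behind `treeheight`, and what the synthetic experiments do and do not show.

## Coordinate and unit conventions

Depth rasters are camera z-depth. Absolute maps are millimeters in
[0, 65535] (the 16-bit sensor range); the value 0 is reserved for "no
measurement", since depth-from-motion maps contain holes and zero is the
only unused distance. Relative maps are unitless 32-bit floats, meaningful
only up to an affine transform; they are stored as float TIFF rather than
8-bit so the alignment fit is never quantized.

Back-projection uses `z = −d/scale`, `x = −(u−cx)·z/fx`,
`y = −(v−cy)·z/fy` with `scale = 1000` mm/m, so points lie at negative z in
front of an upright camera and tree height is a Y-extent. The sign of the
x equation is a free convention — axis-aligned extents are invariant to it
(tested) — and is configurable.

## Affine depth alignment

`A = S·R + D` is fit by ordinary least squares through the closed-form
normal equations over jointly valid pixels (absolute pixel valid AND
relative pixel valid; zero-depth holes would otherwise bias both
coefficients). The result is independent of pixel traversal order. A
negative fitted S is allowed but triggers a warning, since it usually means
an inverted relative-depth convention (disparity-like maps).

An optional robust mode performs one trimmed refit after dropping residuals
larger than 3× the initial RMS; it is off by default. It matters when the
coarse map's depth edges are blurred: pixels straddling a tree/background
boundary can be meters wrong relative to the sharp fine map, and this
contamination attenuates the OLS scale like classical errors-in-variables
(about −5 % under the default synthetic degradation, which inflates
close-range heights beyond the acceptable envelope). The single 3×RMS trim
removes essentially only those edge pixels and restores S to within ~1 %;
the end-to-end degraded pipeline therefore runs with the trimmed refit
enabled.

Applied alignments clamp output to [0, 65535] mm. Degenerate inputs:
fewer than two jointly valid pixels, or constant R (singular design),
raise errors rather than returning NaNs.

Depth quality is quantified by the half mean-squared error
`(1/2M)·Σ(dᵢ−d*ᵢ)²` over the M jointly valid pixels and by δ-threshold
accuracy (percentage of pixels with `max(d/d*, d*/d)` strictly below 1.25).

## Segmentation network

The Depth-Attention-UNet has two parallel encoder streams (3-channel RGB,
1-channel depth), each level applying two 3×3 convolutions + ReLU then 2×
max pooling. Per level the two streams' pre-pooling features are fused and
the fused tensor feeds the decoder's skip connection through an additive
attention gate (gate signal = the upsampled coarser decoder feature;
attention map = `σ(ψ(ReLU(W_g·g + W_x·x)))`, one channel, broadcast over
the skip's channels). Design points that were genuinely open:

* **Fusion operator** — elementwise sum by default (preserves channel
  count, so the decoder matches a single-encoder attention U-Net);
  concatenation + 1×1 projection is a config option.
* **Stream continuation** — after fusion each encoder continues from its
  own unfused features; fusion products are used only for skips and the
  bottleneck. This keeps the modalities decorrelated until the decoder.
* **Loss** — per-pixel binary cross-entropy with logits (the head is
  semantic tree/background); individual trees are recovered afterwards as
  4-connected components ordered by area, with a minimum-area filter.
* **Optimizer** — Adam at the configured learning rate (default 1e-3,
  batch 8, 200 steps, 512×512 input, 64 base channels over 5 levels;
  "total steps" counts optimizer steps).
* **Depth input** — per-image min-max normalization to [0, 1] over valid
  pixels, invalid pixels set to 0; the network needs ordering, not units.

Everything runs on a small reverse-mode autodiff engine written on numpy
(im2col convolutions, gradient-checked against finite differences in the
tests). This bounds practical problem sizes to desk scale: the overfit
smoke test uses 64×64 inputs, 8 base channels, 3 levels and reaches
IoU > 90 % on its four training images within 200 steps in well under ten
CPU-minutes. That demonstrates the architecture and training loop are
sound; it says nothing about generalization to real imagery, which would
require the full-scale dataset and configuration.

Augmentation applies one identical spatial transform to image, depth and
mask: horizontal flip (p = 0.5), uniform scale jitter, random crop resized
back. Mask and depth are resampled nearest-neighbor, so labels stay
integral and metric depth values are never blended or rescaled by a zoom.

## Reconstruction and measurement

Back-projection emits one point per valid pixel in raster order, carrying
color, instance label and source pixel, so clouds are deterministic and
exactly invertible (the reprojection round-trip is tested to machine
precision). Radius outlier filtering retains points with at least
`min_neighbors` other points within `radius` (defaults 1.5 m and 10); the
neighbor count excludes the point itself by default (configurable — at the
default threshold and realistic densities the convention does not change
results). The filter uses a k-d tree, an exact method verified
bit-for-bit against a brute-force O(n²) oracle, and runs a single pass,
not to a fixed point.

Tree height is the raw Y-extent of the axis-aligned bounding box. An
optional percentile trim (default off) guards against a single surviving
noise point setting the height; it is not used in any reported result.
Relative errors are `100·|measured − true|/true`, displayed at 2 decimals
but kept unrounded internally.

## Synthetic scenes

Each scene places cylinder-trunk + crown trees on a ground plane, viewed by
an upright pinhole camera 1.5 m above ground, and is ray-cast analytically
(plane, cylinder and ellipsoid intersections), so the returned depth, mask
and designed heights are exact. Default proportions: trunk 35 % of total
height, crown 65 %, trunk radius max(5 cm, 1.3 % of height), crown
semi-axis 18 % of height.

**Crown shape.** The crown is an ellipsoid truncated flat at 0.65 of its
upper semi-axis. A complete ellipsoid seen from below hides its own apex —
the visible silhouette tangent sits up to several percent of tree height
below the pole — so no surface measurement could recover the designed
height; real crowns are irregular or umbrella-shaped and do expose their
tops. The flat rim lies exactly at the designed height and, because the
rim is a constant-height circle spanning many image columns at varying
distance, it is sampled to sub-pixel accuracy.

**Camera.** fx = fy = 190 px at 512×512 with the principal point at
(256, 365): a wide-angle phone lens "aiming up", the one geometry that
keeps both ends of the validated envelope in frame — the near rim of a
24.4 m crown at 17 m and the ground contact of a 3.7 m tree at 2 m. With
it, rasterization limits noiseless height recovery to ≈0.3 % (about one
pixel's subtended length at the tree distance), comfortably inside the
0.5 % bound the end-to-end tests assert.

**Degradation.** The coarse metric map is emulated by a validity-weighted
Gaussian blur (σ = 2 px; sparse-to-dense reconstruction smears object
boundaries), 1 mm quantization, clamping to [0, 65535] mm and 2 % random
pixel dropout. The fine map is the inverse affine transform of the sharp
truth (S = 80 mm/unit, D = 500 mm) plus prediction error modeled as a
smooth correlated field (0.25 units ≈ 20 mm RMS, 48 px correlation length)
with a small iid term (0.05 units): depth-regression errors are spatially
coherent, and a purely white error would make the bounding-box extreme
statistic grow with point count in a way no real capture shows. An
optional distance-dependent noise term is deliberately not included; its
coefficient would be a free parameter with no principled value.

**What the suite shows.** Over ten seeded scenes spanning 2–17 m and
3.7–24.4 m, exact depth recovers designed heights to < 0.5 % and degraded
depth + alignment to < 5 % (typically ≈0.6–0.8 % mean). These bounds
mirror the error regime reported for real field captures, but the scenes
lack branches, wind, lighting variation, occluding clutter and
segmentation failure modes, so passing them validates the geometry and
plumbing, not field accuracy.

## Problem sizes and determinism

Default test and acceptance runs use 512×512 scenes for geometry,
64×64/8-channel networks for training, 10-scene suites and ≤2000-point
oracle clouds — sizes chosen so the whole suite completes in a few CPU
minutes. Every stochastic component (scene layout, degradation, dropout,
augmentation, batch sampling, weight init) draws from an explicit
`numpy.random.Generator` seeded per call, so reruns are byte-identical.

## Known limitations

* The camera is assumed upright (camera up = world up); tilt would rotate
  the Y axis and bias heights. Real capture rigs report pose; this package
  does not estimate it.
* The alignment is fit per image, not per session.
* Ground points leaking into a mask's trunk base would extend the box
  downward; masks are assumed to exclude ground.
* A tree whose filtered cloud is empty is reported as unmeasurable rather
  than silently dropped.
* The segmentation quality numbers achievable here are overfit smoke
  tests; no pretrained weights ship.
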