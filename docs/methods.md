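# Methods

This note records the models, conventions and numerical choices behind
`grainscan`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what passing the test suite does and does not show.

## Calibration and coordinates

All physical quantities derive from the scanner resolution: a scan at
`dpi` dots per inch has pixel pitch `mm_per_px = 25.4 / dpi` exactly
(0.0423 mm at 600 dpi). The dpi is stored per image, never globally, so
mixed-resolution batches are legal. Pixel coordinates are 0-based and
row-major (y down); bounding boxes are half-open
`[x0, x1) x [y0, y1)`, making `area = (x1 − x0)(y1 − y0)` exact with no
off-by-one. COCO-style `bbox = [x, y, w, h]` is converted to half-open
corners at the I/O boundary. Where a full scanner raster is cropped to a
working field of view, the crop is centred; the position is a package
decision (the offsets are floor-division margins) since nothing in the
imaging geometry prefers one corner.

Dataset splitting shuffles with the caller's seed before slicing
proportionally (remainders go to the earliest parts), because a split
ratio constrains sizes, not assignment order.

## Synthetic panicle scenes

The generator emulates what a flatbed scan of a panicle looks like to the
measurement pipeline — bright, elongated grains on a dark background —
not its photometric detail.

* **Silhouette.** A grain is a rotated superellipse
  `|x/a|^n + |y/b|^n = 1` with exponent n drawn from [2.3, 2.7]
  (default point 2.5). An ellipse (n = 2) is too round and a rectangle
  too square for real grain outlines: the circularity `4πA/P²` implied by
  typical mean area ≈ 18.1 mm² and perimeter ≈ 21.3 mm is ≈ 0.50, which
  falls between the ellipse and rectangle values for an 8.6 × 2.8 mm
  outline; n ≈ 2.5 reproduces it.
* **Population.** Length ~ N(8.607, 0.589²) mm truncated to [5, 11] mm;
  width ~ N(2.770, 0.248²) mm truncated to [2, 4] mm; orientation uniform;
  45–250 grains per panicle in scene batches. These are the measured
  scales and ranges of real panicle populations; a uniform mode exists for
  stress tests.
* **Rendering.** Coverage is computed on a 3 × 3 subpixel grid; the mask
  is the set of pixels with ≥ 50 % coverage, and colours are assigned
  binarily from the mask (grain tone RGB (206, 178, 136), background
  (34, 30, 27)), with optional Gaussian texture noise (sd 5 by default)
  inside the grain only. Binary colouring keeps Otsu segmentation of a
  render exact and makes a noise-free render exactly two-coloured; the
  subpixel coverage still anti-aliases the geometry, so mask areas match
  the analytic superellipse area `4ab·Γ(1+1/n)²/Γ(1+2/n)` to well under
  1 %.
* **Scenes.** Grains are placed by rejection sampling and painted in
  order (later grains occlude earlier ones). With occlusion disabled a
  3-px clearance is enforced so blobs never touch; with a ceiling r, no
  grain's final occluded fraction may exceed r. Scene annotations carry
  full masks, visible masks, exact per-grain traits (analytic area,
  quadrature perimeter) and realised occlusion ratios; visible + occluded
  areas always sum to the full areas.
* **Pairs.** Restoration training/evaluation pairs render one grain
  centred in a square crop (256 px at 600 dpi by default) and slide an
  occluder — a second grain or a thin high-exponent "branch" strip, the
  two occluders seen on real panicles — along a random direction,
  bisecting the offset until the covered fraction of the grain mask is
  within ±0.02–0.03 of the requested ratio. The occluder-shape mix is a
  free parameter of the generator; nothing downstream depends on it
  beyond the realised coverage.

Everything is driven by a caller-supplied `numpy` Generator, so scenes
and pairs are bit-reproducible per seed.

What the generator does **not** emulate: photorealistic texture, awns,
per-variety colour, panicle branching topology, illumination gradients,
or sensor noise in the background. Tests passing on these scenes
demonstrate the pipeline's geometric correctness and its behaviour under
controlled occlusion — not robustness to real-scan photometric variation.

## Grain measurement

The per-grain pipeline is: red channel → Otsu threshold → largest
connected component → outer contour → measurements → derived traits.

* **Red channel.** The R channel is used unmixed; on rice scans it
  carries the strongest grain/background contrast (the synthetic grain
  tone reproduces this).
* **Otsu.** The threshold maximises the between-class variance over all
  256 candidate levels (computed from cumulative histogram sums; the
  smallest maximiser is returned on ties. The test suite checks equality
  with an exhaustive 256-candidate split of the raw pixel array).
  Foreground is `gray > t`. A constant image raises a degenerate-input
  error rather than returning an arbitrary level.
* **Contour.** The largest component is hole-filled and traced with
  marching squares at level 0.5 on a zero-padded raster: a closed,
  simple, subpixel polygon of the outer boundary only.
* **Length** is the maximum pairwise distance between contour points,
  found via convex hull + rotating calipers (an O(n²) brute-force oracle
  covers it in tests); the achieving pair defines the major axis.
* **Width** sweeps section lines perpendicular to the major axis at 1-px
  steps; at each line the chord spans the extreme polygon intersections,
  and the maximum chord is the width. Sub-pixel sweep steps were
  considered and rejected: at grain scale (≥ 60 px across) the 1-px sweep
  already recovers widths within ~1 %. Since every chord joins two
  contour points, width ≤ length holds by construction.
* **Area** is the foreground pixel count of the (hole-filled) largest
  component times `mm_per_px²` — the projection area of the binary mask,
  not the polygon's area (the two differ by the half-pixel boundary band;
  pixel count is the convention that matches mask-based phenotyping).
* **Perimeter** is the arc length of the closed boundary polygon after a
  5-point circular moving average of its vertices. The raw marching-squares
  polygon staircases along diagonal runs and overestimates smooth
  perimeters by ~6 % (a digital disk's circularity would plateau near
  0.90); the 5-point smoothing brings disk perimeters within ~0.5 % of
  2πr while barely rounding true corners. Frozen reference: a filled
  10 × 10 px square measures 36.17 (the hand-count band for reasonable
  tracers is 36–40).
* **Derived traits.** `LW = L/W`, `AP = A/P` (the area/perimeter ratio:
  with the means above, 18.140/21.313 = 0.851), circularity `4πA/P²`
  (≤ 1 up to a 5 % discretisation slack, → 1 for digital disks as radius
  grows), equivalent ellipse = (major = L, minor = `4A/(πL)`), i.e. the
  ellipse sharing the measured major axis and area. The equivalent ellipse
  is an interpretation (the quantity is conventionally named but not
  formula-fixed) and is reported alongside, not inside, the 15-trait
  summary.

**Aggregation.** The 15-trait panicle summary is GN (the number of
measured grains) plus mean/SD of length, width, projection area,
perimeter, area/perimeter ratio, circularity and length/width ratio, in
that order. SDs use the sample convention (n − 1) by default — the
convention is configurable because nothing in the trait definitions fixes
it — and a single grain reports SD 0. Thousand-grain statistics draw
1000 grains without replacement (with replacement plus a warning when the
pool is smaller) and histogram length, width and L/W over fixed bin
edges.

Accuracy at scanner scale (600 dpi), measured by the acceptance script on
500 synthetic grains: length and width MAPE ≈ 0.3–0.6 %, area ≈ 0.06 %,
comfortably inside the 2–3 % bands the tests assert.

## Detection

The **classical baseline** is deterministic: red-channel Otsu, connected
components, then per-blob marker-controlled watershed on the negated
Euclidean distance transform, with markers = connected components of
`dt > 0.5 · max(dt)`. For one convex grain the ridge of the distance
transform is a single connected plateau, so isolated grains are never
split (asserted over 50 seeded scenes); two grains joined at a thin waist
produce two ridge components and are split. Heavily fused clusters
(crossing grains whose junction is thick) defeat ridge splitting, so a
second pass splits any segment larger than 1.75 × the scene's median
segment area into `round(area/median)` parts by deterministic k-means on
pixel coordinates (centres initialised at quantiles along the segment's
principal axis). Within-panicle grain areas vary far less than 1.75×, so
the pass never touches isolated grains. Box scores are segment solidity.
At up to 20 % inter-grain occlusion this keeps count MAPE well under 5 %;
with occlusion disabled counts are exact.

The **trainable detector** keeps the two-stage, pyramid-fused design at a
size that trains on a CPU in seconds: a fixed feature pyramid at strides
4/8/16 (local mean, local SD, gradient magnitude per level, each level
concatenated with its upsampled coarser neighbour and standardised), a
linear objectness head shared across levels (stage 1), and per-proposal
pooled features feeding a linear classifier and box regressor (stage 2).
Training uses class-balanced BCE plus L2 box regression, jointly by SGD
with momentum; stage-2 training proposals are anchored on the ground
truth (one positive anchor per truth box plus a fixed negative grid) so
the objective is stationary across steps. Default hyperparameters —
input 1425 × 1700, NMS IoU 0.74, 4000 proposals, SGD lr 0.02 momentum 0.9
weight decay 1e-4, 100 epochs — are the full-scale training recipe; the
desk-scale tests exercise only the overfit-one-scene contract (loss
strictly below the first step after 25 steps, ≥ 1 predicted box). The
smoke-trained detector is not accurate — the deterministic baseline
carries the measuring pipeline; weights are never shipped.

## Occlusion restoration

The **geometric baseline** takes the occluded crop and the occluder mask,
segments the visible silhouette (Otsu foreground minus occluder), keeps
the boundary points at least 3 px away from the occluder (the cut edge is
occluder geometry, not grain geometry), fits an ellipse by least squares,
and repaints the occluder region: grain tone (median visible grain
colour) inside the fitted ellipse, background tone outside. It requires
≥ 30 % of the crop foreground to be visible and fails explicitly below
that. Observed pixels are never altered, so the restored silhouette
always contains the visible one. An ellipse slightly underestimates a
superellipse's tip, but end- and side-occluded grains at 30 % coverage
recover length within 3 % and width within 5 %.

The **learned restorer** is a conditional GAN: a 3-stage U-Net generator
(channels c→2c→4c with base c = 8, average-pool downsampling, nearest
upsampling, skip concatenation, linear 3-channel output) against a fused
discriminator — three stride-2 and two stride-1 4 × 4 convolutions
yielding a patch logit map with a 70-px receptive field (30 × 30 at
256 × 256), plus a global head (linear on the pooled third feature map)
consuming the same (condition, candidate) pair. Losses: discriminator
BCE real→1/fake→0 on both heads fused 1:1 (configurable); generator
fused adversarial loss toward 1 plus 100 × L1 reconstruction. The L1
term and its weight follow the standard image-to-image translation
formulation; the fusion weights and the optional `patch_grid` pooling
(N = 1 degenerates the patch head into a second global head) are exposed
in config with these defaults. Optimisation is Adam (lr 2e-4, β₁ 0.5);
training is pure numpy, fully deterministic per seed, and reports
divergence (non-finite loss) instead of swallowing it. Default recipe:
256 × 256 inputs, batch 64, 500 epochs; desk tests run the contracts at
64 × 64 and ≤ 200 steps (identity overfit monotone per checkpoint;
one-batch reconstruction and generator losses strictly decreasing;
training-lowers-validation-error). At inference the restorer may be given
the visible-region mask, in which case observed pixels are copied
through; without it the guarantee of silhouette preservation rests on the
trained network alone.

## Evaluation metrics

R², MAPE and RMSE follow their standard definitions on paired
predicted/true vectors (MAPE requires non-zero truths; R² requires
non-constant truths). PSNR uses MAX = 255 and returns an explicit +∞
sentinel for identical images — a legal comparison outcome, not an error;
RGB MSE is averaged over channels. SSIM is computed from **global**
image statistics in a single window, with the standard constants
c₁ = (0.01·255)², c₂ = (0.03·255)² (the defining formula names the
constants without fixing them; these are the conventional choices, and a
sliding-window mode is available behind a flag, default off, for
comparability with windowed implementations). AP matches predictions to
truths greedily in descending score order, each truth used once, at a
given IoU threshold, and integrates the all-points-interpolated PR
curve; with no truths, AP is 1 when nothing is claimed and 0 otherwise.
NMS, Otsu and AP are all covered by independent exhaustive oracles in
the test suite.

## Pipeline

`run` applies detect → (restore) → measure → aggregate per scan. ROIs
are detection boxes padded by 4 px and clipped — a margin consistent with
how single-grain crops are framed for measurement; the hand-off geometry
between detection and restoration is a package decision. When
restoration is enabled, each ROI's occluder mask is the union of the
*other* detected segments inside the window (the learned path instead
receives the grain's own visible segment to preserve). Per-grain
failures are logged and skipped; GN counts measured grains, so the
per-grain CSV row count always equals the summed GN. Outputs embed the
config hash and seed for provenance. `benchmark` generates scenes at a
coarse working resolution (150 dpi on a 1700 × 1425 canvas by default, so
a 250-grain panicle fits the canvas; 600 dpi full-canvas scenes are
available), runs the cascade and scores counts and panicle means against
the generator truth.

Problem sizes in the shipped tests and acceptance script — 500 grains
for recovery, 20 scenes per counting condition, 50 restoration pairs,
64 × 64/≤ 200-step smoke training — were chosen as the smallest sizes at
which the checked statistics are stable; all scale up by argument.

## Known limitations

* The synthetic scenes are geometric stand-ins; no claim is made about
  accuracy on real scans, scanner photometrics, or varieties outside the
  emulated size ranges.
* The trainable detector uses hand-crafted pyramid features with linear
  heads — it honours the architecture and training contracts at desk
  scale but is not a production detector; the classical baseline is the
  accurate path on synthetic scenes.
* The geometric restorer needs the occluder mask (from detection
  segments in the pipeline) and ≥ 30 % visibility; the learned restorer
  removes the mask requirement but is only smoke-trained here.
* Perimeter depends on the boundary tracer and smoothing convention;
  values are comparable within this package (the convention is frozen and
  golden-tested), but cross-tool perimeter comparisons should expect
  percent-level convention differences.
* Mass-based traits (e.g. thousand-grain weight) are out of scope: they
  are not optically measurable from a single scan.
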