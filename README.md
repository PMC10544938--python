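# grainscan

Separating-free phenotyping of on-panicle rice grains from flatbed-scanner
images.

Grain number, length, width, length/width ratio, projection area and
perimeter are core yield- and quality-related traits in rice breeding.
Measuring them usually means threshing the panicle and measuring grains one
by one — slow, destructive, and operator-dependent. An alternative is to
scan the intact panicle with a visible-light flatbed scanner and measure
every grain *in place*, which requires three capabilities: finding each
grain on a crowded panicle, compensating for the parts of grains hidden by
neighbouring grains and rachis branches, and turning each grain image into
calibrated physical measurements.

`grainscan` implements that cascade end to end, for image analysts and
plant-phenotyping researchers:

* **scan_io** — calibrated image and trait-table I/O. A scan at `dpi` dots
  per inch has pixel pitch `mm_per_px = 25.4 / dpi` (0.0423 mm at 600 dpi);
  boxes are half-open `[x0, x1) x [y0, y1)` in 0-based pixel coordinates;
  annotations round-trip through COCO-style JSON.
* **synth** — a synthetic scanned-panicle generator with exact ground
  truth. Grains are rotated superellipses `|x/a|^n + |y/b|^n = 1`
  (n ≈ 2.5) with populations matching real panicles (length
  8.607 ± 0.589 mm in 5–11 mm, width 2.770 ± 0.248 mm in 2–4 mm,
  45–250 grains per panicle, controllable inter-grain occlusion). Every
  scene ships boxes, masks, per-grain true traits and occlusion ratios, so
  each downstream stage can be scored exactly without any data download.
* **detect** — a deterministic classical detector (red channel → Otsu →
  connected components → distance-transform watershed, plus a k-means
  second pass for heavily fused blobs) and a trainable two-stage detector
  with multi-scale feature-pyramid fusion exposing
  `train_step(batch) -> loss` / `predict(image) -> boxes`; greedy NMS at
  IoU 0.74.
* **restore** — occlusion completion. A deterministic geometric baseline
  fits an ellipse by least squares to the visible silhouette's boundary
  and repaints the occluded region; a trainable conditional-GAN restorer
  pairs a U-Net generator (skip connections concatenate encoder features
  into the decoder) with a fused Global + Patch discriminator (a 30 × 30
  patch score map at 256 × 256 input), optimising the fused adversarial
  loss plus an L1 reconstruction term (weight 100).
* **traits** — the measurement pipeline: red channel → Otsu threshold
  (maximising between-class variance over all 256 levels) → largest outer
  contour → length (farthest contour point pair, via convex hull +
  rotating calipers), width (longest chord perpendicular to the major
  axis, swept at 1-px steps), projection area (pixel count), perimeter
  (smoothed boundary arc length), and the derived descriptors
  `L/W`, `A/P`, circularity `4πA/P²`, and the equivalent ellipse
  (major = L, minor = `4A/(πL)`). Per-panicle aggregation yields the
  15-trait summary (GN plus mean/SD of the seven grain quantities) and
  thousand-grain trait distributions.
* **metrics** — R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)², MAPE, RMSE,
  PSNR = 10·log₁₀(255²/MSE), single-window SSIM
  (2μxμy+c₁)(2σxy+c₂)/((μx²+μy²+c₁)(σx²+σy²+c₂)), and detection AP/mAP
  (greedy score-ordered matching, all-points PR interpolation).
* **pipeline** — orchestration (`run`, `benchmark`) and the `grainscan`
  CLI (`simulate`, `detect`, `extract`, `run`, `benchmark`, `evaluate`).

## Worked example

Simulate one panicle with 60 grains and up to 20 % inter-grain occlusion,
run the full cascade (detection → per-ROI restoration → measurement →
aggregation), and compare with the generator's exact truth:

```python
import numpy as np
from grainscan import synth, pipeline
from grainscan.scan_io import mm_per_pixel

rng = np.random.default_rng(0)
mm = mm_per_pixel(150.0)
scene, truth = synth.generate_scene(60, synth.OcclusionConfig(max_ratio=0.2), mm, rng)
result = pipeline.run([scene], pipeline.PipelineConfig(restoration=True),
                      annotations=[truth])
print(result.per_panicle.round(3).to_string(index=False))
print("count MAPE vs truth: %.2f%%" % result.report.extras["count_mape_pct"])
print("mean-length MAPE vs truth: %.2f%%" % result.report.extras["mgl_mape_pct"])
```

prints

```
  panicle_id  GN   MGL   SGL  MGW  SGW   MGPA  SGPA    MGP   SGP  MGAPR  SGAPR   MGC   SGC  MGLWR  SGLWR
panicle_0000  60 8.836 0.642 2.84 0.36 20.364 2.504 19.908 1.317  1.021  0.081 0.646 0.052  3.155  0.431
count MAPE vs truth: 0.00%
mean-length MAPE vs truth: 0.67%
```

All 60 grains were found and measured (GN = 60); the panicle-mean grain
length of 8.836 mm is within 0.7 % of the generating population's truth,
and the remaining columns are the mean/SD pairs of width, projection
area, perimeter, area/perimeter ratio, circularity and length/width
ratio over the 60 grains.

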