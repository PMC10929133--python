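# Methods

## Problem and model

A panoramic radiograph projects the whole dentition onto one image in which
neighbouring teeth overlap. The measurement pipeline assumes two upstream
segmentation outputs: a *position stack* of 32 binary masks (universal
numbering, one mask per tooth, multi-label — a pixel may belong to several
teeth) and a 4-class *region map* (0 background, 1 intrabony root,
2 suprabony root, 3 crown). rblkit's job starts where the segmenter stops.

Per tooth, the radiographic bone loss is modelled as a length ratio along
the tooth's long axis. The long axis is the PCA principal axis of the
tooth's set-pixel scatter: centroid = mean pixel-center coordinate,
covariance with population (1/N) normalization, principal direction = the
eigenvector of the larger eigenvalue. The suprabony and whole-root extents
are obtained by clipping the infinite axis line against the convex hull of
each region (half-plane clipping of a parametric line; by convexity the
intersection is one segment). RBL% = 100·A/B with A the suprabony-hull
length and B the whole-root-hull length; A ≤ B holds mathematically by hull
inclusion, and a clamp guards floating-point noise only. Stages follow the
2018 classification: I below 15%, II in [15, 33), III at and above 33 — the
lower cutoff is exclusive for stage I and the upper cutoff inclusive for
stage III, which forces the half-open stage II interval.

### Design choices that were genuinely open

- **Axis pixel set.** The axis is fitted to the whole tooth (crown + both
  root regions) by default because the enclosing ellipse is a whole-body
  construction; `axis_source="root"` selects the root-only alternative.
  On the phantoms both recover the truth to ~1 point.
- **Axis anchoring.** The axis line is anchored at the whole-tooth centroid
  and treated as infinite before clipping, so A and B are measured on the
  same line even when the centroid lies outside a region's hull.
- **Enclosing ellipse.** The reported ellipse is the PCA-aligned
  circumscribing ellipse (semi-axes √λ scaled by the maximum Mahalanobis
  radius over set pixels), not the true minimum-area enclosing ellipse. Only
  the axis direction feeds the measurement; the ellipse exists for
  visualization and sanity checks.
- **Eigen-direction sign** is canonicalized to a non-negative row component
  (ties: non-negative column) so results are identical across platforms.
- **Degeneracy.** When the relative eigenvalue gap is below 1e-6 the shape
  is near-isotropic and the axis direction numerically arbitrary; such teeth
  are still measured but flagged `DEGENERATE_AXIS`. This is the known
  failure mode of PCA orientation on teeth wider than they are long.
- **Manual distance method.** L3/L4 "vertical" distances are projections
  onto the tooth's long axis, not the image vertical — image-vertical is
  meaningless for tilted teeth. `distance.mode = image_vertical` in the
  config preserves the alternative reading.
- **Stage-II boundary.** 15 belongs to stage II and 33 to stage III (see
  above); thresholds are configurable (`staging.t1/t2`) for sensitivity
  analyses.

## Cascade plumbing

The dental region is one global tight bounding box of all position masks,
expanded by a configurable padding (default 10 px — a small margin protects
hull geometry at crop borders) and clipped to the frame. Per-tooth cropping
is not implemented. Merging intersects each tooth's position mask with each
region label; pixels claimed by several teeth are kept in every claiming
tooth (multi-label semantics throughout). Teeth with a root but no crown
are kept — the measurement needs roots, not crowns; teeth with no labelled
pixels at all are dropped and logged.

## Metrics and losses

Pixel metrics are computed from a single confusion matrix: F1 = 2TP/(2TP+FP+FN),
IoU = TP/(TP+FP+FN) (hence F1 = 2·IoU/(1+IoU), asserted as a property),
accuracy, sensitivity, specificity, precision. Zero-denominator cases return
an explicit `None` marker, never NaN, and are excluded from macro averages
with a logged warning. Macro averages are unweighted means — this choice
reproduces published macro precision/sensitivity staging rows recomputed
from their per-stage values. Segmentation reports pool confusion counts per
class across images (micro within class), then average across classes
(macro); both pooled and macro rows are emitted because aggregation schemes
are rarely stated in the literature. Both losses clamp probabilities to
[1e-7, 1−1e-7]: large enough to avoid −∞, too small to move a reported
value at four decimals.

## Phantom generator

A phantom tooth is a rounded-rectangle crown atop 1–3 linearly tapered
roots (tip width 30% of the top width; multi-root teeth place roots
symmetrically with an inter-root gap of 18% of the root span, which
exercises the hull's gap-bridging). The alveolar crest is a straight line
perpendicular to the tooth axis at fraction *f* of the root length, so
`true RBL% = 100·f` exactly; ABC landmarks are placed at fraction *f* along
the CEJ→AP lines, making both manual formulas exact at zero tilt. The whole
shape and its landmarks are rotated rigidly by the tilt, and rasterization
is center-inclusive (a pixel whose center lies on a polygon boundary is
inside). Default dimensions (crown 40×60 px, root 120×44 px) approximate a
single-rooted tooth at panoramic scale and give ≈0.5-point rasterization
error on a 120-px root.

Boundary jitter for robustness tests flips mask-edge pixels with
probability erfc(0.5/(σ√2)) — the chance that a normal displacement of
s.d. σ (the `jitter_sd` parameter, in pixels) exceeds half a pixel.
Landmarks and stored truth are never jittered.

What the phantoms do *not* emulate: grayscale texture and exposure
artefacts, angular/vertical bony defects (the crest is uniform), furcation
morphology, crown restorations, and the segmentation errors of a real
model. Passing the recovery tests therefore validates the geometry and the
plumbing, not robustness to realistic segmentation noise; the jitter
parameter provides a crude knob for the latter.

## Numerical notes

- Convex hulls use the monotone chain with collinear boundary points
  dropped; degenerate hulls (single point, collinear segment) are legal
  inputs to the line clipper (length 0, or the segment length when the line
  contains it).
- Line clipping tolerances: 1e-12 on half-plane denominators, 1e-9 on
  containment; the dense-sampling oracle in the tests agrees within 0.5 px.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical (spec, seed) pairs reproduce
  phantoms bit-for-bit.

## Validation problem sizes

The test suite and acceptance script use desk-scale cohorts chosen to keep
runs comfortably reproducible on one CPU: 200 phantom teeth for the
correlation/MAE recovery check (Pearson r > 0.95, MAE < 3 points over
fractions 0.05–0.8 and tilts to ±30°), a 45-tooth fraction sweep for
recovering the staging cutoffs by bisection, and 100 random polygon/line
pairs plus 50 brute-force hull comparisons for the geometry oracles.

## Known limitations

- One global dental-region crop; per-tooth boxes are not implemented.
- The circumscribing ellipse is not the minimum-area enclosing ellipse.
- Staging here is the RBL-based severity stage only; no grading,
  progression, or clinical diagnosis is computed.
- Position masks from real segmenters may disagree with the region map near
  boundaries; merging trusts the intersection and flags only empty regions.
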