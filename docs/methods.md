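# Methods

This note documents the models, conventions and numerical choices behind
spikekit, and what its synthetic-data tests do and do not demonstrate.

## Problem setting

Cereal spikes (here: sorghum panicles) in nadir UAV imagery are small
(long sides typically under 100 px at ~0.4 cm/px ground resolution),
elongated, densely packed, and arbitrarily oriented. Axis-aligned bounding
boxes fit them poorly — they admit large background fractions and merge
neighbours — so the pipeline works with *oriented* boxes
(cx, cy, w, h, θ, cls[, score]) throughout.

## Box model and angle convention

* Coordinates are continuous pixels, origin at the image's top-left corner,
  x right, y down. The image spans [0, W] × [0, H].
* θ is the angle between the box's **long** side and the x-axis, in
  degrees. An unoriented rectangle's long axis has a 180° period, so
  normalization enforces w ≥ h and θ ∈ [0, 180): swapping sides adds 90°,
  then θ is wrapped mod 180. Degenerate boxes (w ≤ 0 or h ≤ 0) are
  rejected rather than treated as segments.
* All geometry is computed in the stored frame, so the y-down convention
  is internally consistent; "positively oriented" polygons are those with
  non-negative shoelace sum in that frame.

## Overlap area, rotated IoU, and the duplicate criterion

The overlap of two oriented boxes is computed by clipping one rectangle
against the other (Sutherland–Hodgman, half-plane tests inclusive within
1e−9) and fan-triangulating the resulting convex polygon from its first
vertex; the overlap area is the sum of the triangle areas, which equals the
shoelace value (asserted to 1e−9 relative in tests). Two rectangles
intersect in a convex polygon of 3–8 vertices; touching contact (shared
edge or corner) counts as zero area. Vertices closer than 1e−9 px are
merged.

Two overlap ratios are exposed:

* `rotated_iou` = area(∩) / area(∪), the standard matching score;
* `overlap_ratio_sum` = area(∩) / (area(a) + area(b)) ∈ [0, 0.5], the
  duplicate criterion used by the oriented NMS (0.5 exactly for identical
  boxes).

An independent rasterization oracle (point-in-rectangle counting on a dense
grid over the joint bounding region) validates the clipping IoU; shapely's
polygon intersection provides a second independent route in the unit tests.
shapely is deliberately **not** used for the implementation itself, only as
an oracle; it does supply the minimum-area enclosing rotated rectangle used
by the IO layer (DOTA polygon → box, tile clipping), which is standard
computational-geometry plumbing.

## Circular smooth labels

The long-side angle is treated as one of 180 integer-degree categories.
Plain one-hot labels ignore angular proximity and the 0/180 wrap, so the
encoder produces a circular smooth label: bin k gets
exp(−d(k, θ)² / (2σ²)) when the circular distance d(k, θ) < r, else 0,
with the window wrapped across the period boundary. Defaults r = 6°,
σ = r/3 = 2° (window edge at 3σ); both configurable. The vector is scaled
so its peak is exactly 1 — a no-op for integer angles, and for sub-degree
angles it keeps label semantics (peak = certainty 1) at the cost of ≤ 0.5°
quantization on decode. Decoding is argmax with ties to the smallest index;
an expectation decoder was considered and rejected because the circular
mean is ill-defined for wide or symmetric windows.

`circular_angle_distance(a, b) = min(|a−b| mod 180, 180 − |a−b| mod 180)`
is the metric used for all angle errors, so 179° vs 1° counts as 2°.

## Wise-IoU loss

For an assigned (ground truth, prediction) pair the localization loss is
α · (1 − IoU) with α = exp(((GTx−Bx)² + (GTy−By)²) / (GTw+GTh)²) ≥ 1:
mislocated centers are penalized multiplicatively. The α normalizer is the
ground-truth size exactly as written (no detaching or batch means, as some
Wise-IoU variants use). The IoU inside the loss defaults to the
axis-aligned (x, y, w, h) decoupling — consistent with a pipeline where
angle is handled by classification — with the full rotated IoU selectable
per pair. The loss is a forward evaluation over an explicit pair list;
anchor assignment and gradients are out of scope.

## Reference operators

`deformable_conv2d` and `scaled_dot_product_attention` are plain-numpy
forward passes documenting the operator semantics used by
attention-augmented deformable feature extractors: per-tap bilinear
sampling with zero padding, stride 1, square kernels; softmax(QKᵀ/√d)V
with max-subtracted softmax. Offsets and weights are *inputs* — nothing is
learned here, and network wiring, training and inference on real imagery
are explicitly not implemented. Zero-offset deformable convolution is
asserted equal (≤ 1e−9) to a brute-force direct convolution.

## Oriented NMS

Greedy, score-descending: keep the highest-scored box, discard any
remaining box whose overlap criterion with a kept box exceeds the
threshold, repeat. The criterion defaults to the intersection-over-sum
ratio with threshold 0.25 (half its 0.5 maximum, analogous to the
customary IoU 0.5); the IoU criterion is available. Score ties are broken
by box geometry (cx, cy, w, h, θ) so the kept set is independent of input
order. Suppression is class-agnostic (single class).

## Evaluation metrics

* Matching: predictions in descending score order greedily claim the
  unmatched ground truth of highest rotated IoU ≥ 0.5 (threshold
  configurable). Remaining predictions are FP, unclaimed truths FN.
* mAP: all-points interpolated area under the precision–recall curve
  (precision at recall r = max precision at recall ≥ r); the 11-point
  variant is behind a flag for comparability. One class, so mAP = AP.
* RMSE_a / MAE_a: pooled over all matched pairs across images using the
  circular distance (raw signed difference behind a flag; a per-image-mean
  aggregation variant is also provided since the plain formulas are
  ambiguous about the index set).
* RMSE / MAE: per-image count differences between annotated boxes a_i and
  predictions t_i at an explicit score threshold (default 0: count all).
* Angle metrics are undefined (an error, not 0) with zero matches.

For *metric-recovery* experiments — checking that injected angle noise of
known σ is recovered — pairs are taken from the known generator
correspondence rather than threshold matching: matching at IoU ≥ 0.5
censors the large-error tail of slender boxes (≈2% at σ = 10°, far more at
σ = 20°) and would bias the recovered RMSE downward, conflating the
matcher with the metric. The matcher itself is validated separately.

## Augmentation and dataset splitting

Per input image: rotations by 90/180/270°, horizontal and vertical flips,
and brightness scaling by 0.8/0.9/1.1/1.2 (±10% and ±20%), each applied to
the original (no stacking), plus the original itself — a tenfold
expansion (600 annotated images become 6000). Quarter turns map
θ → (θ+90) mod 180 and swap dimensions; flips map θ → (180−θ) mod 180.
With continuous coordinates the mirror of cx is W − cx (not W−1−cx).
Splitting (default 6:1:3) uses largest-remainder rounding over a seeded
permutation; because splitting happens after augmentation, variants of one
original can land in different parts — a group-by-original split is the
obvious extension when leakage matters.

## File formats and tiling

roLabelImg XML stores the angle in radians; reading converts to degrees
and normalizes (the 180° fold is the only lossy step). DOTA text lines
carry the four corner coordinates plus class and difficulty (ground truth)
or score (detections); corners are refit via the minimum-area rotated
rectangle, and both formats round-trip within 1e−6 px / 1e−4°.

Tiling lays non-overlapping tiles with stride equal to the tile size and
anchors the final row/column at the image edge (a 4032×2268 frame yields
7×4 = 28 tiles of 600²). A box belongs to the first tile (row-major)
containing ≥ 50% of its area; it is clipped to the tile and refit as a
minimum-area rectangle. Because the enclosing rectangle of a clipped
polygon can protrude slightly past the tile edge, the fit re-clips and
refits (geometric shrinkage, ≤ 50 rounds, with a final shrink-about-center
guard) so every emitted box lies inside its tile.

## Synthetic scenes

The generator emulates the *statistics* that matter to this toolkit, not
appearance: default 600×600 px scenes, spike count Poisson(30), long sides
uniform 35–95 px (below 100), aspect ratios 0.22–0.45, and an angle
mixture of 45% wrapped-normal at 0° (σ = 10°), 15% at 90° (σ = 10°), 40%
uniform — a stylized match to field annotation statistics with a dominant
mode at 0°. Placement rejection-samples so no pair of spikes exceeds an
intersection-over-sum ratio of 0.10 (dense but individually resolvable;
safely below the 0.25 suppression threshold). Rendering draws textured
rotated ellipses on a noisy canopy-green background; each annotation box is
the renderer's exact placement rectangle, so geometric ground truth is
exact by construction. Everything is deterministic under a seed
(byte-identical images).

Detection sets for testing are derived from ground truth by a perturbation
model: wrapped-Gaussian angle noise, Gaussian center jitter, multiplicative
size jitter, Bernoulli misses, Poisson false positives placed like scene
spikes; true detections score Beta(8, 2), false positives Beta(2, 5), so
precision–recall curves are non-trivial.

What passing these tests shows: the geometry, label codec, loss, NMS and
metrics are internally correct and recover known injected parameters. What
they do not show: performance on real UAV imagery — occlusion, motion
blur, growth-stage color variation and annotation subjectivity are not
modelled, and no detector is trained or evaluated here.

## Problem sizes and numerics

Default verification sizes were chosen to give tight statistical checks at
desk scale: 500 random box pairs against a 2000²-point rasterization
oracle (|IoU error| ≤ 0.01 required; observed ≲ 1e−4); 110 Poisson(30)
scenes (≥ 3000 boxes) for angle-noise recovery; 100 scenes for the
duplicate-suppression count check; 600 small (96×96) scenes for the
augmentation-factor check, whose 10× expansion is independent of image
size. Geometric tolerance is 1e−9 px for orientation tests and vertex
merging; file round-trip tolerances are 1e−6 px and 1e−4°.
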