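# Methods

## The grading problem

Cataract severity is scored clinically on the LOCS III scales: nuclear
opalescence (NO) and nuclear colour (NC) from slit-beam photographs, cortical
(C) and posterior subcapsular (P) cataract from retro-illumination
photographs. Grade 0 denotes a normal lens; NO/NC run to 6, C/P to 5.
`locsgrade` implements a fully hand-crafted processing chain per modality
followed by a small per-type neural network that maps a short feature vector
to an integer grade.

## Nuclear branch (slit-beam)

**Bright-spot suppression.** Corneal flash reflections and skin highlights
saturate all three channels. A pixel is blackened iff R, G and B all exceed
250 (strictly). The operation is idempotent and touches nothing else. The
threshold is a parameter.

**Binarization.** BT.601 grayscale, then a dynamic global threshold chosen by
Otsu's criterion (`pixel > t` → white). A constant image has no histogram
valley and maps to all-black rather than raising. A manual threshold override
is available.

**Lens localization.** The coarse lens region is the tight bounding box of
the largest 8-connected white component. Inside it, the lens is located as
the inscribed ellipse of maximal area over all axis-aligned rectangles such
that every pixel centre strictly inside the ellipse (`(x-cx)²/a² +
(y-cy)²/b² < 1`) is white. The exhaustive search is O(w²h²) rectangles; the
default enumerates sizes and positions at stride 2 and then hill-climbs at
stride 1 in a ±2 window around the incumbent. Stride 1 is the exact search
(verified against an independently written exhaustive oracle on random
masks); stride 2 is near-optimal but can stop short of the maximum on rare
tie configurations — the trade is a ~16x reduction in candidates. Ties are
broken toward the larger horizontal semi-axis, then the smaller (y, x)
corner, purely to make the result deterministic.

Because a real lens section is not exactly elliptical, the located ellipse is
expanded by a configurable factor (default 1.1, clipped at the frame) before
cropping. The crop is the ellipse's bounding box with outside-ellipse pixels
zeroed, plus the interior mask.

**Features.** For a standard colour `(r, g, b)` and scalar `Offset` the fuzzy
interval is the RGB box `[r±Offset] × [g±Offset] × [b±Offset]` (inclusive
endpoints; no clamping is needed since pixels live in [0, 255]). The feature
is the fraction of lens-mask pixels inside the box. Defaults: standard cyan
(0, 255, 255) for NO, standard yellow (255, 255, 0) for NC, offsets
{40, 80} for each — four features per image. Two offsets give a coarse
radial profile of colour membership without inventing further structure.
Proportions are computed over the elliptical mask only, so background zeros
from the rectangular crop do not dilute them; `include_background=True`
restores whole-crop counting.

## Cortical/posterior branch (retro-illumination)

**Coarse segmentation.** Otsu foreground, largest component, minimum
enclosing circle (exact, via computational-geometry routines; validated
against an O(n³) pair/triple oracle).

**Highlight filling.** All pixels inside the circle are sampled (uniformly,
seeded; default up to 2 000) and clustered into three colour categories by
greedy agglomeration: repeatedly merge the two clusters whose mean colours
are closest in Euclidean RGB distance, replacing them by their
member-weighted mean, until exactly three clusters remain. Identical colours
are collapsed up front (their zero-distance merges happen first and leave
every centroid unchanged), and nearest-neighbour caching makes the loop
O(n²)-ish rather than O(n³). The categories correspond to the orange-yellow
fundus reflex, the white flash highlights and the dark background/lesions;
the yellow cluster is identified as the one maximizing `(R+G)/2 − B`
(configurable), and every highlight pixel — saturated pixels
(`min(R,G,B) > 240` by default) dilated by one pixel to catch the halo —
is painted with the rounded yellow mean. k-means is deliberately not used:
the procedure is defined by the merge loop, and the implementation is checked
against a naive full-recompute agglomeration oracle and cross-checked against
centroid-linkage hierarchical clustering.

**Precise localization.** A circular Hough transform over the boundary of a
fixed-threshold foreground map, radii 0.55–1.15 of the coarse radius. The
normalized accumulator peak must reach a minimum vote fraction (default
0.25), otherwise a "no circle" error is raised.

**Lesion binarization.** Opacities block the red reflex, so lesions are
*dark* structures on a bright disc. A pixel inside the circle is lesion iff
its intensity falls below the local box mean (block = width/8, odd) by more
than `offset_c = 5`; this local rule is robust to the illumination gradient
across the curved eyeball. A lesion wider than the block darkens its own
neighbourhood and would survive only as a rim, so interior holes are filled
morphologically — this makes the centred-disc closed forms (area ratio
(r/R)², perimeter ratio r/R) hold to a few percent. Perimeters use the
Crofton estimate, which is unbiased on discs where the naive boundary count
overshoots by ~5%.

**Features.** Cortical: probabilistic Hough line segments (vote threshold
20, min length 0.2·radius, max gap 0.05·radius), aggregated into a fixed
6-vector — count, total length/r, mean length/r, mean and min perpendicular
centre distance/r, and the foreground fraction inside the circle; no
detected segment gives the zero vector. The aggregation into order- and
count-invariant statistics is this package's choice: the per-line quantities
(length, position, centre distance) vary in number per image but the grader
needs a fixed-length input. A line's "position" enters through its
midpoint-based perpendicular distance to the pupil centre. Posterior:
external contours of lesion components (≥ 8 px, noise-speck filter),
aggregated into [Σarea/πr², Σperimeter/2πr, area-weighted centroid
offset/r, contour count].

## Grading networks

One independent network per type (the two branches have different feature
schemas, and NO/NC proportions live on different colour axes). Architecture:
inputs standardized by the stored training mean/std, one sigmoid hidden
layer (8 units), one sigmoid output unit. The output in (0, 1) is the grade,
rescaled: targets are `(grade − min)/(max − min)`, training is full-batch
gradient descent on MSE, and prediction rescales, rounds half-up and clips.
A single ordinal output was chosen over a softmax because LOCS grades are
ordered and the clinical output is "a point on the scale".

Defaults: 8 hidden units, 20 000 epochs, learning rate 0.5, Xavier-uniform
initialisation from a per-model seed. Plain gradient descent through two
sigmoids converges slowly, and shorter schedules (e.g. 2 000 epochs at 0.05)
demonstrably underfit — training loss stalls around 5·10⁻³, which is one
full grade of RMS error on a 7-grade scale; the chosen schedule reaches
~2·10⁻³ in under a second at these problem sizes. All hyperparameters are
in the run configuration and logged.

**Evaluation.** Confusion matrix over the type's full grade range, per-grade
precision/recall/F1 (0 when the denominator is 0, logged), overall accuracy
= trace/n, and a per-grade "accuracy" column reported explicitly as
one-vs-rest (TP+TN)/n. ROC/AUC from a single scalar score is constructed
one-vs-rest: the score of a sample for grade k is `−|raw − t_k|` with `t_k`
the scaled target of grade k; AUC is trapezoidal and the macro AUC averages
the grades that have both positives and negatives. Note that this
construction is invariant under monotone transforms of the raw score only
for the extreme grades (where the score is itself monotone in the raw
output); for interior grades the folding around `t_k` matters. A
macro-averaged pairwise construction can be substituted.

**Split.** Deterministic seeded 70/30 partition (|train| = round(0.7·n));
the stratified variant apportions per-class train counts by largest
remainder so class proportions are preserved within one item, and singleton
classes go to the training set with a warning.

## Synthetic data

Clinical photograph collections of this kind are not publicly deposited, so
the package ships a grade-controlled generator used by the tests and the
benchmark:

* Slit-beam (144×112): dark background (~12), an elliptical lens slab
  (semi-axes 40×28) of neutral grey pixels of which a fraction is tinted
  cyan (NO) or yellow (NC); the fraction is linear in grade (0 → 0, max
  grade → 0.8) plus Gaussian jitter (sd 0.025). Saturated white corneal
  spots (all channels ≥ 252) and yellow peri-ocular spots are rendered
  outside the lens.
* Retro-illumination (160×160): orange-red pupil disc (radius 52 ± 3,
  centre jitter ± 4) with a multiplicative linear illumination gradient
  (amplitude 0.15, random direction), dark radial spokes (2 per C grade,
  length 0.55 + 0.07·grade of the radius), a dark central plaque covering
  3%·grade of the pupil (relative area jitter sd 0.10), two saturated flash
  spots and Gaussian pixel noise (sd 2).

Grade→signal maps are linear because that is the simplest strictly monotone
choice; the jitter levels were set so that held-out grading accuracy lands
in the high-but-imperfect 0.85–0.95 band, keeping the end-to-end benchmark
informative. Each image carries its ground-truth geometry (lens ellipse,
pupil circle, spoke angles, plaque mask), so localization and angle-recovery
claims are scored exactly.

What the generator does **not** emulate: optical blur and depth-of-field,
specular texture of real highlights, eyelash/eyelid occlusion, mixed-type
cataracts in one eye, vascular shadows, and the grade-frequency imbalance of
clinical practice. Passing the synthetic benchmark shows the chain is
self-consistent and recovers planted signal at realistic noise; it does not
certify clinical performance.

## Problem sizes and runtime choices

The benchmark runs at 30 images per grade (780 images total), retro
clustering samples 800 pixels per image inside the pipeline (the standalone
function defaults to 2 000), and the ellipse search uses stride 2. These
sizes keep a full pipeline run at a few minutes on one CPU while leaving
every statistical conclusion unchanged at larger sizes.

## Degenerate inputs and tie-breaks

* constant gray image → all-black binarization, no exception;
* all-black binary → "no lens candidate" error; no all-white 2×2 ellipse →
  "no lens found" error;
* empty feature mask → explicit error rather than NaN;
* fewer than three distinct colours in the clustering sample → fill with the
  unmasked-region mean, logged;
* empty Hough accumulator or sub-threshold peak → "no circle" error;
* component-area ties → first component in raster order; ellipse ties →
  larger horizontal axis, then smaller (y, x);
* mix-up keeps the dominant-λ image's label (grades are ordinal; averaging
  one-hot labels has no meaning on an ordinal scale).

## Known limitations

* The strided ellipse search is heuristic between grid points (exact only at
  stride 1).
* The one-vs-rest AUC from a single scalar output compresses interior grades
  (see above); reported AUC for middle grades is conservative.
* Hough-line aggregates saturate when spokes overlap heavily at high C
  grades.
* The grading networks are per-type; correlated co-occurring opacities are
  not modelled.
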