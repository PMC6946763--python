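# Methods

`nervequant` implements an automated quantification pipeline for the corneal
sub-basal nerve plexus (SBP) in corneal confocal microscopy (CCM) images:
patch-based U-Net segmentation (single network, or a bootstrap ensemble fused
by pixel-wise majority vote), skeleton morphometry of the segmented nerves,
and the agreement/diagnostic statistics used to validate such a method
against manual annotation and clinical group labels. All components are
exercised on seeded synthetic nerve phantoms with exact ground truth.

## Image standardisation

CCM sources deliver different frames and pitches (e.g. 384×384 px covering
400×400 µm, or 768×576 px covering 460×350 µm). Morphometry in physical
units needs a correct pitch, so standardisation resamples to the working
pitch of 1.04 µm/px by bilinear interpolation *first*, and only then
centre-crops or zero-pads to the 384×384 working frame. When pitch and frame
cannot both be honoured, the pitch wins: a wrong frame only changes the patch
layout, while a wrong pitch biases every length in µm. Anisotropic pitches
(row/column) are carried separately until resampling makes them equal.
Coordinates are 0-based `(row, col)` with row 0 at the top; RGB inputs are
collapsed by BT.601 luminance.

## Patch tiling and stitching

Frames are tiled into 128×128 px patches anchored every 32 px per axis
("stride 32"), which yields exactly 9×9 = 81 patches on a 384 px frame; a
flush anchor at `dim − patch` is appended for frames where the stride does
not reach the border. Stitching is per-pixel majority voting over the
patches covering each pixel: foreground iff positive votes ≥ ⌈c/2⌉ of the
c covering patches. Ties (possible where coverage is even, e.g. 16-fold in
the frame interior) default to foreground, favouring sensitivity for thin
structures; both the tie rule and an alternative probability-averaging mode
(mean sigmoid output, threshold 0.5) are configurable. The identity
`stitch(extract(M)) = M` holds for any binary mask because votes are then
unanimous.

## Segmentation network

The segmenter is a U-shaped encoder/decoder with skip concatenation:
per level, two 3×3 convolution + ReLU blocks; 2×2 max-pooling down and 2×2
nearest-neighbour upsampling + 3×3 convolution up; channels double per level
from `base_channels`; dropout (rate 0.2) after each encoder block and the
bottleneck, disabled at inference; a 1×1 convolution + sigmoid head produces
per-pixel foreground probabilities, binarised at 0.5. Library defaults are
depth 4 and 32 base channels (the canonical shape at 128 px input; the input
side must be divisible by 2^depth).

Training minimises the soft Dice loss `1 − (2Σpt + s)/(Σp + Σt + s)` with
smoothing s = 1 over each batch, using Adam (lr 10⁻³). The hard Dice
coefficient (binary masks, s → 0) is used for reporting; two empty masks
score 1 by convention. Because no deep-learning framework is part of the
supported dependency set, the network is implemented directly in numpy with
explicit forward/backward passes (im2col convolutions over BLAS); gradients
are verified against numerical differentiation in the test suite. All
stochastic elements (He weight init, shuffling, dropout, bootstrap) derive
from explicit seeds, so training is bit-reproducible.

## Ensemble

The ensemble trains `n_members` (default 5, enforced odd so pixel majorities
are never tied) networks, each on an image-level sample-with-replacement
resample of the training set, each with its own weight-init seed; the seed
list is recorded for reproducibility. Bootstrapping at the image (not patch)
level preserves image-level train/test hygiene: no test image contributes
any training patch. Fusion happens after stitching, at the image level:
a pixel is foreground iff ≥ ⌈n/2⌉ members mark it foreground.

## Morphometry

A binary segmentation is thinned to a 1-px skeleton by morphological
(hit-or-miss) thinning to convergence — chosen over the Zhang–Suen pass
because the latter can leave 2×2 junction blocks, which the node classifier
rejects. Skeleton pixels are classified by 8-neighbour count: exactly one
neighbour = tail (terminal) point; ≥ 3 neighbours = branch point, with
8-connected clusters of branch pixels (raster thinning produces 2-px
clusters at crossings) merged to the member pixel nearest the cluster
centroid. Segments are maximal node-free 8-connected paths between nodes;
node-free cycles count as one closed segment each.

Lengths are geodesic step counts times the pixel pitch. `path_length_um`
defaults to chamfer weights (1 orthogonal, √2 diagonal). The aggregate
`quantify` defaults to Kulpa's calibrated digital-line weights
(0.9481/1.3408): chamfer counting overestimates the length of a digital
straight line by ≈ 5.5% averaged over orientations (max 8.2% at 22.5°),
a bias larger than the 5% recovery tolerance this package holds itself to;
the calibrated weights are unbiased to first order (measured on the default
phantoms: +5.4% median error with chamfer, +0.2% calibrated). The chamfer
convention remains available (`length_weights="chamfer"`) for comparison
with tools that use it.

The fractal number is the box-counting dimension of the skeleton: occupied
boxes N(ε) are counted on grid-aligned partitions for dyadic ε from 2 px to
a quarter of the frame, and the reported value is the least-squares slope of
log N versus log(1/ε). Grid offsets are not averaged, keeping the estimator
deterministic; it reproduces the analytic limits (≈1 for a straight line,
≈2 for a filled square). Whether to measure the skeleton or the full
segmentation is a genuine choice; the skeleton is used because it makes the
measure independent of fibre width. An empty mask yields an all-zero record
with the fractal number undefined (NaN).

## Agreement and diagnostic statistics

Per-variable error summaries follow the method-comparison convention
V_i = v_method,i − v_manual,i with RMSE = √(mean V²) and the sample SD of V
(n−1 denominator); the identity RMSE² = V̄² + (n−1)/n·SD² is checked
numerically. Agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measures, computed from the ANOVA mean squares — the
standard form for method comparison because it penalises systematic bias;
bands follow the conventional cut-offs (< 0.5 poor, 0.5–0.75 moderate,
0.75–0.9 good, > 0.9 excellent). Bland–Altman limits of agreement are the
mean difference ± 1.96 SD of the differences, with t-based 95% CIs for the
mean (SE = SD/√n) and for each limit (the classic approximation
SE = SD·√(3/n)); the t rather than normal quantile is used throughout, a
choice that matters only at small n.

ROC analysis enumerates all unique thresholds; AUC is the trapezoid rule
(equal to Mann–Whitney concordance with ties counted ½, verified against an
O(n²) oracle). Because nerve length is *lower* in neuropathy, the score
direction is auto-detected: if the raw AUC is below 0.5 the scores are
negated, the reported AUC is ≥ 0.5, and the flip is recorded
(`orientation = −1`, decision rule "score ≤ cut → positive"). The optimal
cut maximises the Youden index J = sensitivity + specificity − 1; ties are
broken toward higher specificity (a screening context favours fewer false
positives).

## Synthetic phantoms

The generator emulates what makes CCM segmentation hard — bright curvilinear
branching fibres (default 3 px wide) on a noisy, non-uniformly illuminated
background — while keeping exact ground truth. Each nerve tree is a
persistent random walk: seeded at a random border point heading inward
(nerves enter the field of view at its edges), heading perturbed by
N(0, 0.12 rad) per 2 px step; a branch spawns with probability 0.03 per
step, inheriting the position and deviating the heading by 0.9 ± 0.15 rad
(floored at 0.6 rad so the daughter stroke separates quickly). Truth is
stored as sub-pixel polylines: total length is the chord sum × pitch, and
branch/tail/segment counts follow from the tree topology, independent of
rasterisation.

Three constraints keep polyline truth and raster mask in exact
correspondence: trees are drawn sequentially and walkers stop before
touching previously laid fibre (no crossings between trees, which would
create junctions absent from the truth); branch events on one walker are at
least 6 steps apart (junctions never merge into one raster cluster); and a
walker too short to emerge from its parent's dilated stroke is dropped with
its whole subtree. The mask is by construction the rasterised centreline
dilated by a disc of radius (width−1)/2. The rendered image is a Gaussian
fibre cross-section (contrast 0.45) over a background of 0.30 with a
random-orientation tilted-plane illumination field (default 30%
peak-to-trough) plus i.i.d. Gaussian noise (SD 0.08), clipped to [0, 1].

Defaults approximate a healthy SBP frame: 5 trees in a 384 px field at
1.04 µm/px give total lengths broadly comparable to healthy per-image
values (≈ 2000–3000 µm); the fibre-depleted ("neuropathy") preset uses
2 trees and a lower branch rate, reflecting the reduced nerve fibre length
that characterises diabetic neuropathy. Cohort generation derives per-image
seeds from (spec seed, cohort seed, index), so identical specs produce
identical images across groups — useful for null experiments.

What the phantoms do **not** model: keratocytes and dendritic cells, point
spread and optical sectioning, fibre-width variation, tortuosity structure,
and interrupted fibres. Passing the recovery and learning checks therefore
demonstrates the correctness of the pipeline's machinery on images with
CCM-like first-order statistics, not clinical performance on real CCM data.

## Study sizes and numerical choices

The self-tests and the reproduction script run the full study at desk
scale, chosen so the whole suite fits comfortably on one CPU: ground-truth
recovery on 100 default phantoms; training corpora of 12 phantom images at
192×192 px (64 px patches, stride 32, depth-2 U-Nets with 8 base channels,
6 epochs), 4 held-out images; cohorts of 6 + 6 for the ROC check. At this
scale the single network reaches a held-out Dice of ≈ 0.92, the 5-member
ensemble ≈ 0.93 (all-zero baseline 0), and quantified total length
separates the phantom cohorts with AUC ≈ 0.97.

Other numerical choices: binarisation threshold 0.5 on the sigmoid output
(midpoint; configurable); optimiser Adam with lr 10⁻³ (field standard for
U-Net + Dice); the train/test split uses a Mersenne-Twister permutation
followed by a prefix cut, with an optional subject-id column that assigns
whole acquisition sessions to one side.

## Known limitations

- Morphological thinning is not exactly rotation-equivariant: under a 90°
  rotation all counts are preserved exactly but skeleton lengths can differ
  by up to ≈ 1%.
- Near-junction length accounting assigns node pixels to every incident
  segment, so the sum of segment lengths can exceed an idealised total by a
  few pixels per branch point.
- Skeleton-end erosion (thinning a rounded stroke cap recedes the endpoint
  by roughly the stroke radius) shortens each fibre by 1–2 px per end; at
  default widths this is under 1% of typical fibre length.
- No gap reconnection is performed on interrupted fibres, and tortuosity
  and fibre width/area are out of scope.
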