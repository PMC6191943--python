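# Methods

This note documents the models and procedures implemented in `histoquant`,
the choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Tissue-region segmentation

The slide background is bright and nearly uniform; the tissue slice is
darker and textured.  The segmentation therefore works on a heavily smoothed
gray image: the input is bilinearly downsampled so its larger dimension is
at most 5000 px (aspect preserved), converted to luminance with the standard
BT.601 weights (0.299, 0.587, 0.114), median-filtered with a 25×25 kernel
and Gaussian-filtered with σ = 0.5.  Otsu's threshold separates the darker
(tissue) class; the mask is rescaled to full resolution by nearest neighbor.

Smoothing and rescaling leak background-bright pixels into the mask border.
These are removed by an intensity test: with mean_back and std_back computed
over the mask complement, every tissue pixel with gL > mean_back +
0.5·std_back is dropped.  The test is applied to *all* mask pixels, not only
a border band — the intensity criterion itself is the selector, and the
subsequent hole filling repairs any interior punch-through.  The operation
is anti-extensive and, for fixed background statistics, idempotent.

Cleaning then fills holes smaller than 1% of the tissue area, removes
components smaller than `min_area_frac` (default 5·10⁻⁴) of the image area,
and removes spiculated components by a compactness test 4πA/P² <
`min_compactness` (default 0.05).  The perimeter P is the count of exposed
pixel edges (so a square scores ≈ π/4 and a 1-px-wide filament of length L
scores ≈ π/L); this discrete perimeter is exact, orientation-independent and
makes the filament threshold arithmetic transparent.  No reference values
exist for these three thresholds; the defaults are exposed in the API and
chosen so that clean synthetic sections segment with Dice ≥ 0.95.

## Pixel features

A pixel is described by its raw RGB triple plus, per neighborhood size n,
the mean, population standard deviation (divisor N) and range (max−min) of
each channel over the n×n window, with replicate padding at image borders.
The size list is configurable; the default [3, 7] (21 features) brackets the
canonical single-scale 7×7 set (12 features, available as `sizes=[7]`).
Window sums are computed with exact integer arithmetic (separable box
correlation on int64), so feature planes are bit-identical whether computed
on the whole image or on overlapping vertical strips — tiled and whole-image
inference agree exactly, and results are independent of the tiling.

## Training data and cost model

Three annotation classes: marker pixels (label 1), critical not-marker
pixels (negatives whose appearance mimics the stain — ink, blood, folds, and
in the synthetic bed also the tissue pixels immediately adjacent to marker
dots, whose window statistics are marker-like), and rectangles of obvious
negatives.  Typical counts are ~150 / ~150 / ~15000, i.e. a positive:negative
ratio ≤ 1/50.  The 2×2 cost matrix charges Cost(1|true 0) = 1−(Nneg+Ncrit)/N
and Cost(0|true 1) = 1−Npos/N (N the total), so the off-diagonals sum to 1
and the minority class always carries the larger cost.  Cost-sensitivity is
realized as class weights proportional to these off-diagonals — the
expected-loss-equivalent formulation — for both decision trees and the SVM.
The KNN layer is not cost-sensitive (unit costs).

Annotations travel in a CSV (`image,kind,row,col,row1,col1`) with 0-based,
row-major coordinates and half-open rectangles; a pixel annotated as marker
is excluded from any rectangle it falls in (disjointness wins).

## The classifier cascade

Four layers in fixed order — DT, DT, RBF-SVM, 3-NN — applied as a rejection
cascade: a layer that rejects a pixel is final; acceptance defers to the
next layer, so the overall acceptance set is the intersection of the four
layers' acceptance sets, and per-layer workload is monotonically
non-increasing.

Training builds each DT by a fold-wise candidate selection: `folds`
candidates (10 for the DTs, 2 for the SVM), each trained on ⌈Npos/folds⌉
random positives and min(⌈Nneg/folds⌉, 5·Npos) random negatives and
validated on the remaining pixels with plain (unweighted) accuracy; the
candidate with maximum validation accuracy wins (first on ties).  Degenerate
fold draws are retried with fresh randomness up to 5 times.  Hard-negative
mining connects the layers: after DT1 is trained on everything, only the
obvious negatives it misclassifies (false positives) pass to DT2; the
obvious negatives DT2 still gets wrong pass to the SVM; the KNN sees only
those that survived all three.  Critical negatives are never mined away —
they are retained by every layer.  The SVM selects C ∈ {1, 10, 100} and
γ ∈ {scale, 0.01, 0.1} inside its 2-fold selection, and its obvious-negative
pool is capped at 20·Npos by seeded subsampling to bound the fit cost.  The
KNN uses K = 3 on raw RGB with Euclidean distance (no ties are possible with
two classes and K = 3).  A layer left with no negatives at all degrades to
accept-all with a warning.

The raw marker mask keeps only tissue pixels accepted by all layers;
8-connected components with fewer than 3 pixels are then removed as noise.

## Distance histograms and intersection

Marker position relative to a structure border is summarized by the
normalized histogram of each marker pixel's exact Euclidean distance (via
the exact Euclidean distance transform) to the nearest border pixel, in
half-open bins [k·w, (k+1)·w) with default width 1 px; pixels beyond a
band limit (default ∞) are excluded before normalization.  Histograms over
an image set are averaged bin-wise — each image weighs equally regardless of
marker count — and two histograms are compared by the mean of the two
directed intersections Σmin(a,b)/Σb, which for normalized inputs reduces to
Σ min.  Histograms with band ∞ have data-dependent length; equality of bin
structure is enforced on (width, band) and shorter frequency vectors are
zero-padded.

## Serial-section registration

Sections are rigid glass-slide preparations, so a similarity transform
(tx, ty, θ, isotropic scale about the image center) is fitted per section —
no shear or deformation.  The search is multiscale: masks are halved until
the larger dimension is ≤ 256; at the coarsest level the transform is
initialized from centroid alignment plus the principal-axis angle difference
(with ±90° alternates) and refined by greedy coordinate descent on mask
Dice, with step sizes halved down to 0.25 px / 0.1° / 0.002; estimates
propagate up the pyramid with finer steps.  Masks are warped with
nearest-neighbor resampling (binarity preserved; areas re-counted after
warping).  Two guards make registration safe: a pair whose final
full-resolution overlap does not beat identity falls back to identity, and a
set whose GTRO would decrease reverts entirely, so GTRO_after ≥ GTRO_before
always.  On synthetic blobs the search recovers planted transforms within
~0.2 px, ~0.1° and ~0.001 scale — comfortably inside the 2 px / 1° / 0.02
acceptance bands.

## Concentration regions and co-existence

Per section, the histogram of tissue-pixel distances to the nearest marker
pixel (1-px bins, strict `<` comparisons throughout) yields R_MAX — the
center of the first maximal bin — and R_LIMIT — the largest integer r such
that fewer than 50·A_M pixels lie at distance < r.  R = min(R_LIMIT, R_MAX),
floored at 1 px.  Cores are tissue pixels at distance < R/2; core components
with area < 10(R/2)² are deleted; surviving cores are expanded to the
connected components of the distance-< R mask that contain them (preventing
a core from annexing unrelated sparse areas), and expanded components with
area < 20R² are discarded.  Distances are computed for tissue pixels only;
pixels outside the tissue never join a region.  An empty result is a valid
outcome (the section has no concentration region).

The pairwise measures (DM_C, DM_iInCj, PM_iInCj, w, wMean_Dens, wMean_AVG)
are pixel-count ratios as defined in the README.  CA in DM_C is the
section-total concentration area (one density per section's region set); the
per-region breakdown is also reported.  A ratio with zero denominator is
reported as NaN, never as 0 — zero would assert "no co-existence", a
different claim.  Note that wMean_AVG = 100% for identical marker masks
*requires* every marker pixel to lie inside a concentration region; isolated
dots whose cores are area-filtered legitimately lower the measure.

## Synthetic test bed

The generator renders: a smooth closed tissue blob (wavy-radius ellipse,
gray level 190) on a bright background (gray 240) with i.i.d. per-channel
Gaussian noise σ = 4 and salt-and-pepper noise at rate 10⁻⁴; marker dots
(discs, default radius 1) from a truncated per-channel Gaussian color model,
default mean (180, 60, 50), σ = 12, placed uniformly, in planted Gaussian
clusters, or at explicit centers, always 8-disconnected from one another;
and ink-like distractor blobs at the tissue border with mean color
(120, 60, 50), σ = 12 — deliberately only 60 gray levels from the marker in
R, mimicking resection-margin ink.  Serial sets warp one base blob by known
similarity transforms; marker layouts are per-section (or shared, for
co-existence identity checks).  Everything derives from one integer seed and
is bit-reproducible.

What the bed does *not* emulate: real stain texture (DAB granularity,
hematoxylin counterstain), illumination gradients, color variation across
scanners, tissue folds, and out-of-plane structure change between serial
sections.  Passing tests therefore demonstrate correctness of the
algorithms and their implementations under controlled conditions, not
clinical segmentation accuracy.

## Problem sizes and defaults

Synthetic sections default to 300×300 px (400×400 for cluster geometry
studies) with ~25000-px tissue and ~600 marker pixels, annotation samples of
up to 150 marker / 150 ink / 150 halo pixels and four 20×20 negative
rectangles per image — the annotation budget and positive:negative imbalance
a manual session produces.  These sizes keep every property exercised (edge
effects, mining attrition, cap-binding in R estimation) while the full suite
and the study script run in minutes on one core.

## Known limitations

- The similarity model cannot absorb local deformation between sections;
  strongly deformed sets converge to the best rigid fit and show it in GTRO.
- R estimation assumes 1-px distance bins; anisotropic resolutions are not
  modeled (resolutions are carried as metadata only).
- Histogram intersection compares distance distributions, not absolute
  marker counts: two markers at equal distances but very different densities
  intersect at 1.
- The cascade classifies pixels independently; no spatial regularization is
  applied beyond the <3 px component filter.
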