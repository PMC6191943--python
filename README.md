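# histoquant

Trainable segmentation, quantification and comparative analysis of marker
stains in histochemical (HC) and immunohistochemical (IHC) slide images.

Pathology research routinely asks: *how much* of a marker (CD3, CD8, CD163,
Ki-67, ...) is present in a tissue section, *where* does it sit relative to
structures of interest, and — when serial sections of one tissue block are
each stained for a different marker — *do two markers concentrate in the same
tissue volumes*?  `histoquant` answers these questions with deliberately
simple, fast, annotation-trainable image processing, so it can be retargeted
to any stain color without color normalization or deep models.

## What it computes

**Tissue region.** The slice is darker than the slide background: downsample
(max dimension ≤ 5000 px), convert to gray, smooth heavily (25×25 median +
Gaussian σ = 0.5), Otsu-threshold (tissue = darker class), then remove
background-bright border pixels with gL(p) > mean_back + 0.5·std_back, fill
small holes, drop small or non-compact components, and crop.  The tissue
area `TA` is the mask's pixel count.

**Marker pixels.** Each pixel is described by its RGB color plus the mean,
standard deviation and range of each channel over n×n neighborhoods
(default n ∈ {3, 7}).  A four-layer rejection cascade — two cost-sensitive
decision trees, a cost-sensitive RBF SVM, and a plain 3-NN on raw RGB —
classifies every tissue pixel; a pixel is a marker only if **all** layers
accept it.  Training uses three annotation classes (marker pixels, critical
not-marker pixels whose color mimics the stain, rectangles of obvious
negatives) and hard-negative mining: each layer after the first is trained
only on the negatives its predecessor got wrong.  Misclassification costs

    Cost(1 | true 0) = 1 − (Nneg+Ncrit)/N,   Cost(0 | true 1) = 1 − Npos/N

charge more for mistakes on the minority class.  Components under 3 px are
removed from the final mask `M` (area `A_M`).

**Quantification.** Density `DM_T = A_M / TA`; normalized histograms of each
marker pixel's Euclidean distance to a structure border (optionally within a
band), mean histograms over image sets, and histogram-intersection
similarity Σᵢ min(h1ᵢ, h2ᵢ).

**Serial sections.** Tissue masks are aligned with a similarity transform
found by coarse-to-fine overlap maximization; alignment quality is the
global tissue-region overlap `GTRO = 100·A(∩ᵢTᵢ)/A(∪ᵢTᵢ)`.  Per section, a
concentration radius `R = min(R_LIMIT, R_MAX)` is estimated from the
histogram of tissue-to-marker distances, and *concentration regions* are
grown from cores (distance < R/2, area ≥ 10(R/2)²) expanded to distance < R
(area ≥ 20R²).  Pairwise co-existence measures follow:

    DM_Ci    = A_Mi / CA_i                 PM_1InC2 = A_{M1∩Conc2} / A_M1
    DM_1InC2 = A_{M1∩Conc2} / CA_2         w = min(DM_C1,DM_C2)/max(DM_C1,DM_C2)
    wMean_AVG  = w·(PM_1InC2 + PM_2InC1)/2
    wMean_Dens = w·(DM_1InC2 + DM_2InC1)/2

All measures can be restricted to a rectangular ROI (densities then use the
ROI area).  Since serial sections are *neighboring* slices, overlap after
registration indicates co-existence in a tissue volume, not molecular
co-localization.

A seeded synthetic generator (`histoquant.synthetic`) renders tissue blobs,
stain-colored marker dots/clusters and ink-like distractors with exact
ground truth, so the whole pipeline is testable without clinical slides.

## Worked example

Run the full pipeline on a synthetic three-section serial set (sections
related by known shifts/rotations):

```python
from histoquant.pipeline import run_pipeline

run_pipeline({
    "seed": 1,
    "stages": ["simulate", "tissue", "train", "segment",
               "quantify", "register", "coexist"],
    "simulate": {"n_sections": 3, "transforms": [
        {"tx": 0},
        {"tx": 12, "ty": -8, "theta_deg": 4},
        {"tx": -10, "ty": 6, "theta_deg": -3},
    ]},
}, workdir="demo")
```

This writes, among other artifacts, `registration.json`:

```
"transforms": [..., {"tx": -11.34, "ty": 8.76, "theta_deg": -3.875, "scale": 1.0}, ...]
"GTRO_before": 65.92,  "GTRO_after": 98.99
```

— section 2 was planted at (tx=12, ty=−8, θ=4°) and the recovered transform
is its inverse to within a fraction of a pixel; registration lifts the
three-way tissue overlap from 66% to 99%.  `densities.csv` holds the marker
density of each section (`DM_T` ≈ 2.29–2.30% here), and
`coexistence_pairs.csv` the pairwise measures, e.g. for sections 1 and 2:

```
w = 0.978, PM_1InC2 = 0.276, PM_2InC1 = 0.222, wMean_AVG = 0.243
```

meaning each marker's concentration regions capture ~22–28% of the other
marker — the expected moderate co-existence for two *independently placed*
uniform dot layouts.  Identical layouts yield `wMean_AVG = 100%`.

The same stages are available as CLI subcommands
(`histoquant {simulate|tissue|train|segment|quantify|disthist|register|coexist|overlay|run}`).

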