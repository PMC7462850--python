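# Methods

This note records the models, the synthetic study design, the numerical
choices, and the limits of what the test suite demonstrates.

## Pipeline model

The slide classifier is a three-stage pipeline.

1. **Semantic segmentation of patches.** Patches extracted strictly inside
   sparse annotations are labeled with a full-frame one-hot map of a single
   class. The five-class scheme (cancer, benign, other tissue type,
   high-grade-PIN-like mimicker, other) exists to give the network explicit
   negatives for benign mimickers of cancer; at evaluation time all
   non-cancer classes are collapsed. Patch extraction is grid-based inside
   each polygon (default stride = half the footprint); the containment test
   accepts a patch when its four corners and center are covered by the
   polygon (boundary inclusive), with a strict box-in-polygon mode behind a
   flag. Class balance is restored by augmentation multipliers
   `min(cap, ceil(n_max/n_c))` with cap 10 — rarer classes are oversampled
   with photometric/geometric jitter rather than discarding data.
2. **Whole-slide likelihood mapping.** The slide is tiled at the analysis
   magnification; a tile is classified when ≥ 5% of its footprint is tissue,
   otherwise it receives a fixed background distribution (all mass on
   "other"). Edge tiles are reflect-padded and cropped back. The tumor area
   TA is the strict per-pixel argmax of the cancer class (ties excluded, so
   TA ⊆ {TPM > 1/5}).
3. **Slide scoring and ROC.** T07 — the fraction of TA pixels with
   TPM ≥ 0.7 — is the slide score; an empty TA scores 0 (no tumor-argmax
   evidence means no cancer evidence under screening semantics; the ratio is
   otherwise undefined). Mean/std/variance features are computed over TA
   pixels (a `stats domain` choice; the cumulative histogram makes T07
   literally its 0.7 bin). Thresholding is inclusive (`score ≥ t` →
   cancer). AUC is trapezoidal over all unique score thresholds with ±∞
   endpoints, which equals the Mann–Whitney statistic including tie credit.
   Bootstrap CIs are percentile intervals over resampled prediction
   indices (default 2000 resamples); resamples that lose a class are
   redrawn. P3 accuracy uses observed prevalence; accuracy ties resolve to
   the lower threshold (higher sensitivity), the screening-appropriate side.

## Network implementation

No deep-learning framework is used: the package contains a small numpy
engine (`wsiscreen._nn`) with stride-1 same-padding convolutions (im2col),
2×2 pooling, nearest-neighbour upsampling, spatial dropout, instance
normalization, and manual backpropagation, verified against finite
differences in the test suite. Consequences worth knowing:

* Everything is CPU-bound and sized accordingly; the reference
  configurations (U-Net depth 5 with 64…1024 filters at 512 px; DenseNetFCN
  with 5 dense blocks / growth 16 / 4 layers at 256 px) are constructible
  and train correctly, but the shipped experiments use reduced
  configurations (below).
* SGD uses momentum 0.9 (a conventional default; the optimizer's momentum
  is otherwise unconstrained by the reference description). Early stopping
  monitors validation loss by default and restores best-epoch weights;
  Dice (cancer-vs-rest) and accuracy are logged every epoch.
* Two stabilizers keep norm-free SGD training reliable across seeds:
  model inputs given as [0,1] are centered to [-1,1] inside the models
  (on bright, high-mean histology-like images an uncentered input lets an
  early momentum overshoot kill the ReLUs, leaving the net stuck at the
  uniform-prediction loss), and gradients are clipped to a global norm of
  5.0 (`TrainConfig.clip_norm`).
* The cycle-GAN uses Adam (β₁ = 0.5) — least-squares adversarial losses
  with SGD are markedly less stable; the published step-decay learning-rate
  schedule (0.0005, ×0.5 every 20 epochs) is kept.

## Synthetic study design

Real multi-center prostate cohorts are proprietary, so the
`synthetic_data` module generates cohorts with the statistical structure
the pipeline assumes:

* **Slides** are near-white (intensity 245) rasters carrying star-convex
  tissue regions, one procedural texture per class (distinct base/blob
  colors, blob correlation lengths and densities). Textures are meant to be
  learnable by a small CNN, not to look like histology. A two-level
  pyramid with mpp metadata is produced to exercise pyramidal I/O
  (default raster 4096², nominal mpp 0.97).
* **Sparse annotations** are centroid-shrunk copies of a subset of regions
  covering 30–60% of each region's area; cancer slides always carry at
  least one cancer annotation, mirroring the labeling rule that slide
  labels derive from the presence of cancer.
* **Prevalence** is 25% cancer at the slide level via seeded Bernoulli
  draws; per-slide seeds derive from one master seed by splitmix64 hashing,
  so cohorts are reproducible and order-independent.
* **Scanner styles** transform a rendered slide by hue rotation, saturation
  / brightness / contrast scaling, Gaussian blur (or unsharp masking) and
  sensor noise, in that fixed order. The study pair is a near-neutral
  "scanner A" (development domain) and a washed-out "scanner B"
  (hue +40°, saturation ×0.5, brightness ×1.2, contrast ×0.7, blur
  0.5 px, noise 1). Scanner B is deliberately strong: real inter-scanner
  differences are not quantified anywhere usable, and the B style is
  chosen so that a model trained on A actually exhibits the cross-scanner
  performance drop the normalization stage exists to repair. Suppression
  of detection on this cohort requires washing out the color contrast the
  textures encode — pure hue rotations or darkening, however large, leave
  the trained classifier's ranking intact and would make the normalization
  experiment vacuous.

## Desk-scale experiment sizes

The shipped experiments (`wsiscreen.pipeline`) are sized for a single CPU:

| knob | value |
|---|---|
| slide raster | 1024 × 1024 px |
| cohort | 40 training + 20 held-out slides, 25% prevalence |
| patch size / stride | 32 px / 32 px, ≤ 350 patches per class |
| segmentation model | U-Net depth 3, base 8 filters, dropout 0.1 |
| training | SGD lr 0.005, momentum 0.9, batch 8, ≤ 20 epochs, patience 8, gradient-norm clip 5 |
| cycle-GAN | 32-px patches, generators depth 2 / 12 filters, 60 epochs × 40 iterations, batch 4, 5 slides per domain |
| slide normalization | 32-px tiles, 8-px ramp-blended overlap |

The screening run finishes in ~2 minutes and the normalization run in
~6 minutes on one CPU. The cross-scanner slides are the *same* 20 held-out
slide layouts re-rendered under scanner B — the re-scanning scenario — so
style is the only varying factor. The domain gap is likewise measured
content-controlled: source patches from the scanner-B renders are compared
with the scanner-A renders of the same slides at the same coordinates
(160 patches), which isolates the style distance from slide-composition
differences; unpaired small samples mostly measure which classes happened
to be drawn.

One deviation from the usual cycle-GAN recipe: the generators carry **no
instance normalization**. At 32-px training patches the per-patch channel
statistics are dominated by tissue content, and normalizing them destroys
the absolute color identity the translation must preserve — with instance
norm the generator collapsed all tissue classes toward one average color
(diagnosed by per-class mean-color comparison on paired renders).
Without it the translation reproduces per-class colors to within a few
intensity levels. Discriminators are unaffected.

## Numerical choices and conventions

* Coordinates: 0-based, top-left origin, half-open regions; region reads
  address (x, y) at level 0 with (w, h) at the requested level.
* Dice/Jaccard of two empty masks is defined as 1.0 (all-negative
  validation patches must score as perfect agreement).
* MRMR: features are discretized into 3 equal-frequency bins; mutual
  information is the plug-in contingency estimate, rounded to 12 decimals
  so exact ties break toward the lower feature index deterministically.
* Tissue masking: saturation Otsu OR intensity < 0.9·white at ≤ 1024 px
  working width, minus components < 64 px, holes filled.
* GAN image range: [−1, 1] with tanh output; uint8 conversion rounds and
  clips.
* The cohort runners redraw the label sequence (seed bump) in the rare
  event a drawn cohort is single-class, since ROC analysis is undefined
  otherwise.

## What the tests do and do not show

The oracle suite (T07, AUC, MRMR, patch-grid geometry, bootstrap coverage)
establishes exact correctness of the statistics on their own terms. The
end-to-end runs establish that the pipeline *machinery* — sparse-patch
training, tiled inference, T07 scoring, GAN normalization — composes
correctly and that style normalization recovers cross-scanner performance
on cohorts whose class structure is color/texture-separable. They do not
demonstrate clinical performance: synthetic textures have no nuclear or
glandular morphology, no compression artifacts, no annotation noise, and a
far easier class geometry than H&E tissue. Numbers from the synthetic
studies (e.g. held-out AUC) characterize the implementation, not prostate
cancer detection.

Known limitations: convolutions are stride-1 only (downsampling is
pooling); no GPU path; pyramidal TIFFs are read whole into memory (fine at
desk scale, unsuitable for clinical gigapixel slides); vendor-proprietary
slide formats are out of scope.
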