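# Methods

This note documents the models, conventions and numerical choices behind
`histoscreen`, and what its synthetic experiments do and do not show.

## Problem setting

The package implements a screening pipeline for whole-slide histopathology
rasters: decide per slide whether it contains cancer (so benign slides can
be excluded from human review), and in the lesion-detection setting also
localize each metastasis.  Two slide-level read-outs are provided, mirroring
the two clinical shapes of the problem:

* **Percentile screening** (biopsy-style): a slide is scored by the
  likelihood value at which the normalized cumulative histogram of its
  cancer-likelihood map reaches a chosen percentile.
* **Lesion detection** (sentinel-node-style): the likelihood map is
  thresholded and split into connected components; the slide score is the
  highest component median likelihood, and components are matched to
  annotated lesions for FROC analysis.

## Pre-processing

Optical density per channel is `OD_c = -log10(max(I, 1) / 255)` (base-10
Beer-Lambert convention; the clamp at intensity 1 bounds the OD at
`log10(255) ≈ 2.407`).  A pixel is tissue when **any** channel's OD exceeds
0.2; near-white glass background falls below this threshold in all three
channels.  Polygon annotations are rasterized with the even-odd rule using
a strict pixel-center-inside test (pixel centers at integer coordinates,
x right, y down); the half-open ray-casting convention settles centers that
fall exactly on a ring edge.  These conventions make every mask
reproducible by a brute-force oracle, which the test suite exploits.

## Patch extraction and augmentation

Training patches are 128 × 128 RGB squares at the analysis resolution
(configurable; the synthetic experiments analyse at the native simulated
resolution).  A patch's label is the annotation value at its **center
pixel** — the hard-example boosting rule is defined through the center
pixel, so the label must be too.  Sampling is class-balanced and uniform
without replacement within each class; requests that cannot be satisfied
fail loudly with the available counts.  Each patch is expanded into the
8 elements of its dihedral orbit (4 rotations × horizontal mirror), so
augmentation multiplies the dataset exactly by 8.

Boosting draws additional patches after an initial model has produced
likelihood maps for the training slides: candidates whose center pixel the
initial model misclassified (likelihood ≥ 0.5 for benign centers, < 0.5
for cancer centers) receive sampling weight `boost_factor` (default 5)
against 1.  Boost draws are taken **with replacement** — hard examples may
legitimately appear more than once — and are balanced per class across the
whole training split.  The 0.5 cutoff and the single multiplicative weight
are package conventions; both are exposed as configuration.

## Network and training

The default classifier is a small patch CNN: four valid 3 × 3 convolution
blocks (16/32/64/128 filters), each followed by ReLU and 2 × 2 max
pooling, then three dense layers (256/128/2) and a softmax.  On a 128 px
patch the spatial chain is 128 → 126 → 63 → 61 → 30 → 28 → 14 → 12 → 6.
The network is implemented directly in numpy (channels-last, im2col
convolutions, momentum SGD); inputs are normalized per channel to [0, 1]
by dividing by 255.

Training is SGD with momentum 0.9, learning rate 3 × 10⁻³ (chosen for
stable convergence of small-batch momentum SGD at this scale; 10⁻² was
observed to oscillate), batch size 64.  After each epoch the validation
misclassification rate is computed; training stops once it has not
strictly improved for `patience_epochs = 5` consecutive epochs, and the
weights of the best epoch are restored.  The stopping rule is factored
into `simulate_early_stopping` so its semantics can be tested on injected
error sequences.

## Dense whole-slide inference

For whole-slide application the dense layers are rewritten as convolutions
(the first over the remaining 6 × 6 spatial extent, the rest 1 × 1),
yielding a fully convolutional network whose output grid has stride
2^(#pools) = 16 pixels.  Because every convolution is valid and pool
windows start at even offsets, the dense output at grid position *p*
equals the patch network's class-1 probability for the 128 px patch
starting at pixel 16 *p* — this patch/FCN equivalence (tolerance 1e-5,
typically ~1e-7 in float32) is the core correctness oracle of the model
module.  The slide is padded with white background (value 255) by half a
patch on each side so border tissue receives predictions; full-resolution
maps are produced by nearest-neighbor assignment from the stride grid, and
non-tissue pixels are set to zero.  Maps are therefore invariant to
enlarging the background margin by multiples of the stride.

## Slide scoring

The cumulative histogram uses 100 equal bins on [0, 1], half-open with the
final bin closed, restricted to tissue pixels and normalized by their
count.  Restricting to tissue makes the score independent of how much
glass surrounds the specimen (background is likelihood 0 by construction,
so including it would only dilute the histogram).  The percentile score is
the upper edge of the first bin whose cumulative value reaches the
percentile; it is non-decreasing in the percentile by construction.  The
operating percentile can be selected on a validation cohort over the
decile grid {0.1, …, 0.9} by maximum ROC AUC or by maximum specificity at
a sensitivity target (default 0.999); ties break toward the lower
percentile.

## Lesion detection

Maps are binarized at likelihood 0.3 (inclusive comparison), components
are extracted with 8-connectivity (4-connectivity available), and
components with maximum Feret diameter below 0.02 mm — 10% of the 0.2 mm
lower bound of a micro-metastasis — are discarded as spurious.  Diameter
is the maximum pairwise pixel-center distance plus one pixel extent,
computed exactly up to 3000 pixels and via the convex hull above that
(the hull preserves the farthest pair).  Component likelihood is the
median of the raw map values over the component's pixels; the slide score
is the maximum component likelihood, zero when nothing is detected.
Size classes follow the clinical conventions: ITC < 0.2 mm,
micro-metastasis 0.2–2 mm, macro-metastasis > 2 mm.

## Evaluation

A lesion counts as detected when a component overlaps it with Dice ≥ 0.5;
each lesion is claimed by at most one component (highest Dice, ties broken
by higher median likelihood then lower component id).  Any component not
matched at Dice ≥ 0.5 is a false positive even if it partially overlaps a
lesion — a strict reading that keeps the criterion single.  FROC curves
sweep all observed component likelihoods; sensitivity read-outs at an FP
budget use the highest achievable operating point at or below the budget
(step convention, no interpolation).  When ITCs are excluded from an
analysis they leave the denominator, components matched to them are
ignored outright, and ITC-only slides count as tumor-negative for the FP
denominator (configurable choice).

ROC analysis uses the trapezoidal AUC, which equals the Mann-Whitney
concordance probability with ties counted 1/2; specificity at a
sensitivity target is read at the first curve point reaching the target.
Confidence intervals are slide-level percentile bootstraps (default
10,000 resamples; the synthetic experiments use 500–2,000 for speed) with
the equal-tailed 2.5–97.5% interval; resamples on which a metric is
undefined (e.g. single-class) are redrawn and counted, and curve bands use
vertical averaging on a fixed FPR grid.

## Synthetic slides

The generator emulates the three compartments the pipeline must separate:
near-white background (mean RGB ≈ (245, 245, 243), sd 2, floored at 236 so
every channel's OD stays below 0.2), benign tissue (eosin-pink mean
(185, 120, 175) with spatially correlated Gaussian noise, sd 10 per
channel after smoothing), and lesions whose color mean is shifted along a
fixed direction by `texture_separation` × sd; the red-channel component of
the shift has magnitude 1, so a separation of *s* moves the red mean by
exactly *s* pooled standard deviations.  Above the documented threshold of
3 the classes are at least 3 pooled sd apart.  Lesions are star-shaped
blobs with low-frequency boundary harmonics whose maximum through-center
width is scaled to the requested diameter; planted diameters land within
±10% of the request.  Lesions never overlap, never touch the image
border, and the tissue region holds exactly the requested pixel fraction.
Optional distractor blobs (a configurable fraction of the lesion shift,
absent from the annotation mask) create false-positive pressure for
boosting experiments.

The generator deliberately omits nuclei, glands, stain variation and
scanner artifacts.  Passing tests therefore demonstrate that the pipeline
machinery is correct and that the CNN can learn a color/texture contrast;
they say nothing about performance on real H&E appearance variation.

## Study conditions of the synthetic experiments

The end-to-end experiment uses 60 training/validation slides (30
lesion-bearing) and a 20-slide held-out test set; slides are 384 px
squares at 8 µm/px (a 3.1 mm field), with one 0.8 mm lesion per positive
slide, 65% tissue fraction and texture separation 4.  Training draws 12
patches per class per positive slide (augmented ×8), and the default CNN
trains up to 12 epochs.  These sizes were chosen as the smallest cohort at
which slide-level AUC and lesion-level FROC are stable; unit tests use a
further-reduced 256 px / 64 px-patch configuration.  All randomness is
threaded from a single experiment seed through named substreams, so
identical configurations reproduce identical reports.

## Known limitations

* The numpy CNN is CPU-oriented and small; it is a faithful but miniature
  stand-in for production-scale networks.
* Non-integer resampling ratios fall back to anti-aliased resizing rather
  than exact area averaging (integer ratios are exact block means).
* The FCN receptive field of the default topology covers 126 of the
  128 patch pixels (a consequence of valid convolutions with floor
  pooling); patch and dense paths are identical in this respect.
* Boosting improves hard-negative handling only when distractor texture is
  actually confusable with lesions; with very high texture separation both
  runs saturate.
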