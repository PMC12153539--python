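# Methods

This note records the scientific and numerical choices behind
`slidemil`, the assumptions they rest on, and what the synthetic studies
can and cannot demonstrate.

## Problem setting and model

A whole-slide image carries one weak label — benign or metastatic — and
is represented as a bag of patch feature vectors.  The multiple-instance
assumption is asymmetric: a metastatic slide contains *at least one*
tumour-bearing (witness) patch, a benign slide contains none.  The
classifier must therefore both detect rare positive instances and remain
invariant to the number and order of patches.

The model is gated-attention ABMIL.  Patch features (dimension D) pass
through a ReLU projection (D → H1).  Two parallel branches — tanh and
sigmoid, H1 → H2 — are multiplied elementwise and mapped to a scalar
score per patch; a softmax across the bag yields attention weights in
[0, 1] summing to 1.  The attention-weighted sum of projected features is
classified by a linear layer with one output node per class, followed by
a softmax.  The gated variant is used (rather than plain tanh attention)
because it is the default attention head of the CLAM family of weakly
supervised slide classifiers, which this pipeline follows; the
multiplicative gate lets the model modulate which feature directions may
contribute attention.

Exact consequences of this architecture, all enforced by tests: slide
probabilities are permutation-invariant and duplication-invariant;
attention is permutation-equivariant; a single-patch bag receives
attention weight 1; identical patches receive uniform weights.

## Training

Optimisation is class-weighted cross-entropy minimised by Adam
(β₁ = 0.9, β₂ = 0.999), one bag per step with per-epoch shuffling.
Defaults: learning rate 2 × 10⁻⁴, L2 weight decay 10⁻⁵ on weight
matrices (not biases), dropout 0.25 on the projected features, early
stopping on validation loss with patience 20 after a minimum of 50
epochs, maximum 200 epochs, and inverse-frequency class weights
(training cohorts in this setting are typically imbalanced).  These are
CLAM-lineage defaults; every one is overridable through `TrainConfig`.
Hidden sizes default to (512, 256) and scale down to (D, 128) when the
feature dimension D is below 512, so toy descriptors do not get
overparameterised heads.

The implementation is plain numpy with hand-derived backpropagation — no
autograd framework is required, CPU suffices, and the backward pass is
verified against central finite differences (tolerance 10⁻⁶) in the test
suite.  Training is a pure function of the data and the config seed:
shuffling and dropout masks are drawn from one seeded generator, so
identical inputs reproduce identical parameters bit for bit.

## Segmentation and tiling

Tissue is segmented on a 16× block-averaged view: HSV saturation, median
blur with a radius-2 disk, threshold 8/255, morphological closing
(radius 2) and removal of connected components under 16 mask pixels.
The threshold is the convention of the CLAM lineage; the blur suppresses
salt noise.  Raising the threshold can only shrink the mask (closing and
small-object removal are monotone), a property under test.

Patches are enumerated on a grid anchored at (0, 0) with stride equal to
the patch size; boxes crossing the slide boundary are discarded rather
than padded (padding would fabricate background texture), and a box is
kept when its mask tissue fraction is ≥ 0.5 — low enough to keep
edge-of-tissue patches that may contain small foci, high enough to drop
mostly-glass tiles.  Reading a patch area-averages 1024 px → 256 px
(linear factor 4), the 40× → 10× apparent magnification convention; on
synthetic slides the same geometry is expressed in µm/px (default
1 µm/px) with a 256 → 64 px demo configuration, since all geometry flows
through mpp rather than magnification names.

## Feature extraction

Extractors are pluggable: an extractor is an (id, dimension, patch →
vector) triple, and pretrained encoders can be registered at run time.
The shipped descriptor is deliberately simple and fully deterministic
(62 components: RGB/HSV channel means and standard deviations, a 16-bin
grey histogram, mean Sobel gradient, the fraction of pixels darker than
grey level 0.35 — a surrogate for nuclear density — and 4×4 grids of
grey and saturation block means).  It is *not* a learned encoder and
makes no claim to histological generality; it exists so that the
generator's tumour texture (dark nuclei on hue-shifted stroma) is
linearly separable from plain tissue, which the tests verify with an
instance-level linear oracle (AUROC ≥ 0.9).

Bags are stored one HDF5 file per slide (feature matrix + aligned
coordinate table + extractor id), the container convention of CLAM-style
pipelines; loading validates dimension and extractor against the
consuming model.

## Evaluation protocol

Splits are stratified at the case level: unique cases are divided into
five label-stratified folds; fold *i* tests on fold *i*, validates on
fold *i*+1 (mod 5) and trains on the rest — the 60-20-20 split.  Each
case is tested exactly once, so pooled out-of-fold predictions cover
every slide once.  Hold-out slides are scored by averaging the five
models' probability vectors; ensemble AUROC uses the mean metastatic
probability.  Case overlap between hold-out and training data is a hard
error.

Metrics: accuracy, balanced accuracy (mean of class recalls), AUROC in
the Mann–Whitney formulation (ties half-credited; computed through
scikit-learn, and checked against exhaustive pair counting for n ≤ 12),
and F1.  Reported F1 is the metastatic-class F1; the macro average is
also emitted because the averaging convention differs across reports.
Any 0/0 ratio is reported as NaN, never silently as 0.

Uncertainty is a percentile bootstrap over slides: resample with
replacement, recompute, report replicate mean and 2.5/97.5 percentiles
(default B = 10,000).  The resampling unit is the slide because hold-out
sets contain one slide per patient.  Replicates that draw a single class
(undefined AUROC/balanced accuracy) are redrawn up to 100 times; if more
than half the replicates stay undefined the bootstrap aborts with an
error.  Percentile rather than BCa intervals are used — the simplest
interval consistent with "mean and 95% CI from bootstrapping".  For
linear statistics such as accuracy the replicate mean is unbiased for
the point estimate, which the suite checks at B = 10,000 against a
3-standard-error Monte-Carlo bound.

## Heatmaps

For visualisation the slide is re-tiled with 50% overlap (stride = half
the patch size) and the attention head is evaluated over the full
overlapping patch set.  Raw attention scales as 1/N and is incomparable
across slides, so scores are converted to within-slide percentile ranks
before display.  Overlap is resolved by per-pixel arithmetic mean
(order-independent and idempotent for uniform scores); uncovered pixels
stay transparent.  The colormap is blue (low) → red (high), composited
at alpha 0.4 over a 16× thumbnail.  Rank normalisation, mean blending
and the alpha are display conventions, not inferences.

## Synthetic data: what it emulates, and what it does not

`generate_slide` renders near-white background (saturation < 0.02),
overlapping eosin-pink elliptical tissue blobs (saturation ≥ 0.45 — the
gap makes saturation segmentation testable against ground truth), and,
on positive slides, tumour foci as hue-shifted discs scattered with dark
nuclei-like dots.  Focus diameters are specified in µm (default cohort
range 120–350 µm, log-uniform, including the ~100 µm scale at which real
metastases become inconspicuous).  The first tissue blob has a
guaranteed minimum size so that any focus up to roughly half the short
canvas dimension fits; cohort generation validates this up front.
Cohorts group slides into cases (1–3 slides each, uniform) so that
case-level splitting is genuinely exercised, and write ground-truth
masks beside every slide.

`generate_feature_bags` skips imaging: background instances are standard
normal in D dimensions; witness instances shift every coordinate by the
effect size (default 2, i.e. 2σ per dimension — strongly separable by
construction), with witness count 3 per positive bag (or a witness rate),
bag sizes uniform on [20, 50], dimension 32.

These defaults define the package's study conditions.  What passing
tests show: the implementation correctly recovers planted signal —
segmentation reproduces the generating mask (Jaccard ≥ 0.90), the
trained attention concentrates on witnesses (≥ 90% of positive test
bags) and on tumour regions (majority of positive slides), and the
end-to-end chain is reproducible bit for bit.  What they do not show:
performance on real H&E tissue, where staining variation, artefacts,
morphological diversity and far weaker feature separability dominate;
real attention maps are also known to attend to contextual architecture
rather than tumour alone.  The synthetic studies are correctness
verifications, not performance claims.

## Problem sizes

Default study sizes were chosen so the whole verification suite runs
comfortably on a single CPU: the demo cohort uses 768² px slides
(28 training / 12 hold-out) with 256 px patches read at 64 px, and the
bag study uses 100/40/40 bags.  Larger canvases, 1024-px patches and
10,000-resample bootstraps are the same code paths with different
configuration values.

## Known limitations

* Slides are single-level rasters; multi-resolution pyramid formats must
  be converted (or an adapter written) before use.
* The shipped descriptor is a verification instrument; scientific use on
  real WSIs requires registering a pretrained encoder.
* No stain normalisation, augmentation, artefact/pen-mark exclusion or
  blur detection; these sit outside the pipeline's scope.
* The instance-level clustering objective found in some CLAM variants is
  deliberately absent: the model here is attention + classifier only.
* Bootstrap CIs quantify sampling variability of the evaluated cohort
  only; they say nothing about centre-to-centre generalisation.
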