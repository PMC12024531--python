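# Methods

## Problem and scope

`euslite` implements a lightweight convolutional classifier for telling
gastrointestinal stromal tumors (GIST) from leiomyomas on endoscopic
ultrasound (EUS) images, together with everything the workflow around such a
model needs: rotational augmentation about the probe center, a
speckle-aware training recipe, patient-grouped cross-validation,
diagnostic-metric evaluation with size stratification, and Grad-CAM
saliency.  The clinical image collections this kind of model is trained on
are not publicly distributable, so the package ships a synthetic EUS phantom
generator that stands in for them; every pipeline stage is exercised
end-to-end on phantoms.

## The architecture family

The canonical network is a stack of seven convolution units.  Each unit is a
valid convolution (stride 1, no padding), batch normalization with affine
terms, a ReLU, and a 2x2 average pooling.  At a 360x360 single-channel
input the kernels are (9, 5, 5, 5, 3, 3, 2) and the channel chain is
1→32→32→64→128→256→256→256, which produces the spatial chain
352→172→82→37→16→6→2 before pooling (pooling floors odd sides, e.g. 37→18).
The last unit ends at spatial side 1, so a single 256→2 linear classifier
behind dropout (rate 0.8) completes the model.  Counting convolution
weights+biases, batch-norm scale+shift and the classifier gives exactly
1,434,658 trainable parameters; without the batch-norm terms the total is
1,432,610 (the difference, 2,048, is twice the summed channel counts).  Both
counting modes are exposed because per-layer tables conventionally list only
convolution parameters while framework enumeration includes batch-norm.

The family crosses depths 5/6/7 (codes A/B/C) with final widths
64/128/256/512 (codes 1–4); C3 is the canonical model.  Design choices the
family definition needed but that are not fixed by the canonical instance:

* **Activation**: ReLU after each batch normalization (parameter-free, so it
  does not disturb the parameter accounting).
* **Channel schedule for non-canonical members**: 32, 32, then doubling
  capped at the family width; the final unit is forced to the family width so
  the classifier input always equals it (this matters only for A4, where
  doubling alone cannot reach 512 in five units).
* **Kernel schedules**: depth 5 = (9,5,5,3,3), depth 6 = (9,5,5,5,3,3),
  preserving the canonical 9x9 opening kernel and 3x3 tail.
* **Classifier bridge**: family members whose chain ends above spatial side 1
  get a global average pool before the linear layer; for the canonical chain
  this is an identity (flattening a 1x1 map), so C3 is unaffected.
* **Dropout position**: a single dropout on the pooled feature vector, in
  front of the classifier.

A depth bound follows from the pooling geometry: each unit at least halves
the side, so at input side `s` at most `floor(log2 s)` units fit (8 at 360).

Desk-scale siblings (`build_desk`) instantiate the same unit pattern at 96 px
(kernels 9,5,5,3,2) and 64 px (kernels 9,5,5,3) with a lighter 16-channel
stem; they exist because the full 360-px model is needlessly expensive for
CPU-scale experiments and tests.  At non-canonical input sides the family
builder shrinks kernels from the tail and skips pooling at side 1 so every
chain stays valid.

## ResNet-18 baseline

The comparison baseline is the standard ResNet-18 topology with two changes:
the stem convolution takes one grayscale channel and the head outputs two
classes.  Counting all trainable parameters (convolutions, batch-norm affine
terms, classifier) gives 11,171,266 — about 7.8x the lightweight model.  The
package carries both a declarative layer table (for exact accounting) and a
trainable instantiation in its own engine; the two are asserted equal, and
the table is additionally cross-checked against closed-form arithmetic for
the published 3-channel/1000-class variant (11,689,512).

## The CPU CNN engine

No deep-learning framework is part of the dependency set; the package brings
its own compact engine (`euslite.nn`): float32 NCHW arrays, convolution
lowered to BLAS matrix multiplication via im2col, hand-written backward
passes, Adam with classic L2 weight decay, and softmax cross-entropy.
Numerical design points:

* The input-gradient of a stride-1 convolution is computed as a transposed
  convolution (full correlation with the spatially flipped, channel-swapped
  kernel), which keeps the GEMM inner dimension fat; a col2im scatter path
  covers strided convolutions and very large unfold buffers.  First-layer
  convolutions skip the input gradient entirely.
* Batch normalization uses batch statistics in training and exponential
  running estimates (momentum 0.1) at evaluation; its backward pass supports
  both modes, because saliency backpropagates through an evaluation-mode
  forward.
* Dropout is inverted (scaling by 1/(1-p) at train time); its random stream
  comes from the run seed.
* Every backward pass is verified against central finite differences in the
  test suite, and parameter enumeration is asserted equal to the closed-form
  counts.

The engine is single-threaded NumPy, so seeded runs are bit-reproducible.

## Augmentation geometry

EUS frames are rotationally symmetric about the probe, so augmentation
rotates each raw frame about the probe center by fixed increments (default
22.5 degrees, i.e. 15 extra variants, 16 images per raw frame) and then
trims a 360x360 crop centered on the probe — rotation before trimming, so
crops contain no blank corners.  The identity crop is a pure sub-array
anchored at the rounded probe center (no resampling); rotated crops are
sampled directly on the raw grid with bilinear (default) or nearest
interpolation, which is mathematically identical to rotating the full canvas
first.

The "no blank corners" guarantee is geometric, not automatic: the rotated
corner radius of a 360-px box is 180·√2 ≈ 254.6 px, which can exceed the
margin of a 500x400 frame whose probe center has only a 200-px margin.  The
default policy therefore validates all four rotated corner positions per
angle and raises a margin error; reflect-padding with a warning is an
explicit opt-in.

Normalization statistics (population mean/std over all pixels flattened
together) are computed on the training portion only and then applied to
validation/test data — computing them over the whole dataset would leak
test intensities into training-time preprocessing.

## The phantom generator

Each phantom frame is built in three stages:

1. **Envelope**: a dark probe disc with a bright rim at the frame center,
   concentric echogenic wall rings (default radii 6/9/13/18/26 mm at
   echogenicities 0.35/0.75/0.45/0.60/0.30), and a hypoechoic elliptical
   lesion (base echogenicity 0.22) at a seeded offset from the probe.
2. **Point-spread blur**: Gaussian, sigma 1 px.
3. **Speckle**: pixel-wise multiplication by a unit-mean gamma field with
   shape `L` (looks; default 25, variance 1/L), the standard fully developed
   multiplicative speckle model, clipped to [0, 1].

Class contrast is purely structural: leiomyoma-like lesions are homogeneous
with sharp regular margins (heterogeneity = irregularity = 0); GIST-like
lesions carry a smooth random internal texture (amplitude 0.3 x
heterogeneity, default 1.0; correlation length scaled to the lesion radius
so small lesions still contain a few texture cells) and a low-order harmonic
perturbation of the margin (relative amplitude 0.35).  Mean lesion intensity
is identical for the two classes, so a classifier must learn texture/margin
structure; zeroing both knobs for both classes removes the signal entirely,
which is the package's no-signal control.  Contrast defaults were chosen
once so that a desk-scale training run separates the classes cleanly, and
they are all config-exposed.

Cohorts assign each synthetic patient one class (exact balance by default)
and one lesion size from a truncated normal — targeting a mean of 9.3 mm
(scale 5.7) for development-style cohorts and 18.7 mm (scale 10.7) for the
held-out-style preset, truncated to [4, 35] and [3, 50] mm respectively.
Truncating at a positive lower bound inflates the mean of a naive truncated
normal, so the location parameter is solved such that the truncated mean
equals the configured mean; the observed standard deviation is consequently
somewhat below the nominal scale (≈3.7 mm at development defaults) — mean
fidelity is preferred because cohort summaries report means.  Several frames
per patient vary lesion orientation, offset and eccentricity.  Desk frames
are 128x128 at 3.5 px/mm.

What the phantom does **not** emulate: acoustic shadowing, depth-dependent
gain, anisotropic speckle correlation, probe artifacts other than the
central disc, anatomy beyond concentric rings, or any relation between
lesion size and malignancy.  Passing phantom tests therefore demonstrates
that the pipeline is mechanically and statistically sound, not that the
classifier reaches clinical performance on real EUS data.

## Training recipe

The canonical configuration follows the study protocol: Adam, initial
learning rate 5e-5 halved every 250 epochs, batch size 32, cross-entropy,
weight decay 1e-5, dropout 0.8, 2000 epochs at 360-px input.  Where sources
disagree on the weight decay (1e-5 vs 1e-4), 1e-5 is the default and the
value is config-exposed.

The desk preset — what the test-suite and examples run — is the package's
own scale-down: 96-px input, learning rate 5e-4 halved every 15 epochs, 60
epochs, dropout 0.5, batch 32, plus random quarter-turn augmentation in the
training loop (exact `rot90`, the resampling-free special case of the
rotational augmentation).  On the default 200-image phantom cohort this
reaches ~92–95% held-out accuracy in ~4 minutes on one CPU core.

Splitting is patient-grouped everywhere: the 7:3 train/validation split and
the 5-fold cross-validation partition patients, never images, so no patient
contributes to both sides.  Cross-validation selects the median model: the
fold whose final validation accuracy is the rank-⌈k/2⌉ value (for even k the
lower of the two middle values); ties are broken by the lowest final
validation loss.  The reported mean is the arithmetic mean of fold
accuracies.

The ablation runner trains base and variant arms on identical data and
seeds for three regularizers: dropout rate, batch normalization (removed
while dropout and weight decay are retained), and L2 weight decay.  The
overfitting readout is the final train-minus-validation accuracy gap, with
training accuracy measured by a clean evaluation-mode pass.  The ResNet-18
probe uses the same loop via `train_network` with the baseline recipe
(lr 5e-4 halved every 20 epochs; weight decay 0.05 or 1e-5).

## Evaluation

GIST is the positive class throughout.  Metrics with zero denominators are
reported as explicit `None` markers, never silently 0 — small size strata
make this reachable.  Confidence intervals are Wilson score intervals (the
interval method is a package choice; it behaves well at the small
denominators involved).  ROC curves come from a threshold sweep
(scikit-learn) with trapezoidal AUC, which equals the Mann-Whitney rank
statistic with ties counted 1/2; the test suite asserts that equality
against an O(n²) concordance oracle.

Size stratification cuts at 20 mm (`lt20mm` / `ge20mm`) and computes per-
stratum metrics for each prediction source (model, endoscopist labels when
supplied).

`reconstruct_confusion` inverts printed summary percentages: it enumerates
every (tp, tn) grid over the known class totals and keeps those whose
recomputed metrics round (half-up, one decimal) to the printed values.  For
the 66:43 held-out composition with sensitivity 93.9 / accuracy 94.5 /
PPV 96.9 / NPV 91.1 the unique solution is (tp 62, tn 41); a printed
specificity of 95.4 is inconsistent with any integer count (41/43 rounds to
95.3), and the routine reports that near-miss instead of forcing agreement.

## Grad-CAM

The original formulation: channel weights are spatial means of the target
logit's gradient at a unit's pooled output; the map is the rectified
weighted activation sum, min-max normalized.  A constant raw map normalizes
to all zeros rather than dividing by zero.  Maps can be taken at every conv
unit (native sides 176/86/41/18/8/3/1 for the canonical model) and
optionally bilinearly upsampled to the input side.  Saliency on an untrained
model is permitted but flagged in the map metadata.  Enrichment scoring
compares mean heat density inside vs outside a known lesion mask.  Because
chains ending at spatial side 1 produce a constant final-unit map,
localization claims are made at the deepest unit that retains spatial extent
(side ≥ 3: CONV6 for the canonical model, which is also the deepest layer
such models are conventionally visualized at), with the target class set to
the frame's own class — heat for the GIST logit has no reason to sit inside
the lesion of a leiomyoma-like frame.

## Problem sizes used by the tests

Stochastic properties run at fixed seeds on desk-scale problems chosen as
the package's own presets: learnability and the no-signal control on 200
images (50 patients) at 96 px; the dropout ablation and ResNet-18 probe on a
memorization-prone 60-image, 64-px, heavy-speckle (L = 4) preset; grid and
cross-validation mechanics on 50-image, 64-px cohorts with short epoch
budgets.  All randomness flows from explicit seeds, and the engine is
single-threaded, so these checks are reproducible runs, not distributional
claims.

## Known limitations

* The phantom is a structural caricature of EUS; no clinical claim follows
  from phantom performance.
* The engine is CPU-only and unsuitable for 360-px, 2000-epoch training;
  the canonical recipe is retained for fidelity but is not exercised at full
  scale.
* `train_network` on a custom (non-family) network returns a model wrapper
  whose architecture spec is a placeholder; checkpoint round-trips are only
  supported for family/desk architectures.
* Per-patient aggregation of predictions is limited to what the evaluation
  API exposes; the default unit of evaluation is the image.
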