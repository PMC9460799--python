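# Methods

This note documents the models and procedures drowsinet implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Problem and inputs

The package targets frame-level drowsiness classification (alert vs drowsy)
from facial images, in three input representations built from a frame plus
per-eye landmark coordinates:

| input type   | shape        | construction |
|--------------|--------------|--------------|
| `face`       | 28 x 28 x 3  | whole frame, bilinear resize |
| `eye`        | 32 x 64 x 3  | each eye crop resized to 16 x 64, left stacked above right |
| `fusion`     | 32 x 96 x 3  | 32 x 32 face thumbnail concatenated left of the eye pair |
| `eye+gender` | 37 x 64 x 3  | eye pair plus a 5-row constant strip (0 = male, 255 = female) |

Eye crops come from the landmark extrema box, padded by a configurable
margin (default 0.25 of the box extent per side) and clipped to the frame.
Conventions chosen here because no external standard fixes them: (row, col)
coordinates, 0-based half-open boxes, left eye on top, face block left of
the eye block, bilinear interpolation for all resizing. All composite
builders are lossless: slicing a composite recovers each source block
bit-exactly. Landmark detection itself is out of scope — landmarks are an
injected dependency (or ground truth from the synthetic generator).

Network inputs are rescaled from [0, 255] to [0, 1]. The input-side batch
normalization makes the model insensitive to this affine choice.

## The CNN

One fixed architecture for every input size:

    BN -> Conv 32@5x5 (same, stride 1) + LeakyReLU(0.3) -> BN -> MaxPool 2x2
       -> Conv 64@3x3 (same, stride 1) + LeakyReLU(0.3) -> BN -> MaxPool 2x2
       -> Flatten -> Dense 512 + LeakyReLU(0.3) -> BN -> Dense 2 + SoftMax

Parameter accounting: conv layers have k·k·c_in·c_out + c_out parameters,
dense layers n_in·n_out + n_out, batch normalization 4 per channel of which
2 (scale, shift) are trainable and 2 (running mean/variance) are not. The
flatten width after the two poolings is ⌊rows/4⌋·⌊cols/4⌋·64, which is what
separates the three variants' totals (trainable 1,629,320 / 4,217,992 /
6,315,144 for face / eye / fusion).

The network is implemented directly in numpy: im2col + GEMM convolutions
with hand-derived backward passes for every layer, kept in float32 for
training speed (float64 available for gradient-check tests). This makes the
whole gradient path explicit — the same machinery that trains the model
computes the Grad-CAM gradients, and both are validated against central
finite differences.

Numerical/convention choices:

* "Convolution" is cross-correlation (no kernel flip), the universal CNN
  framework convention; parameter counts are unaffected.
* Batch normalization adds its epsilon to the variance (1e-3, inside the
  square root); subtracting it would reintroduce division by zero for
  constant channels.
* A batch normalization layer sits *before* the first convolution (12
  parameters = 4 x 3 input channels), then one after each conv block and
  one after the 512-unit dense layer.
* Max pooling uses pool 2x2, stride 2, dropping a trailing odd row/column
  (relevant only for the 37-row gender-signal input). Gradient at exact
  pooling ties is split among the tied positions; with continuous
  activations ties have measure zero.
* Weight initialization: Glorot-style uniform, fan-based, from a recorded
  seed; biases zero. Identical seed + data + config reproduces identical
  weights bit-for-bit.
* Softmax is max-shifted; the training loss applies the standard fused
  softmax + cross-entropy backward.

## Training and evaluation protocol

* Optimizer: plain SGD (no momentum — none is specified for this recipe),
  staircase learning-rate schedule `0.01 * rate^floor(step/1000)`, decay
  rate 0.9 for the fusion model and 0.75 for the eye model. No rate is
  published for the face model; it defaults to 0.75 (flagged in config).
* A hard cap on optimizer steps (default 10,000) serves as the stopping
  rule; no validation-based early stopping is used.
* Batch size is not externally specified; default 32, configurable. The
  test suite and examples use small batches (4-8) so that full experiments
  run on one CPU core in minutes; with batch normalization the task remains
  stable at these sizes.
* Cross-validation: four *independent* subject-level stratified 70/30
  train/test resamples (not disjoint K folds). Splitting is by subject —
  frame-level splitting would leak subject identity into training, which is
  precisely the face-recognition confound this analysis is designed to
  expose. The test partition size is 30% of all subjects, spread across
  classes by largest remainder.
* Reporting: per-class accuracy at the 0.5 operating point on the drowsy
  probability, their unweighted mean (default) plus a frame-weighted
  variant, ROC by threshold sweep and trapezoidal AUC. Metrics are averaged
  over the four iterations; ROC/AUC plots use the best iteration.

## Grad-CAM

For class score y^c — the pre-softmax logit by default (a softmax-score mode
exists behind a flag) — and the last convolution's activated output A
(16 x 32 x 64 for the eye model: the second conv is applied after one
pooling), channel weights are spatial means of dy^c/dA, and the map is
ReLU(sum_k alpha_k A^k), bilinearly up-sampled to the input size. "Last conv
output" is taken *after* its LeakyReLU, matching the fused conv+activation
layer convention of mainstream frameworks. Gradients are exact (manual
backprop through the network head), tested against finite differences.

Display normalization is per-image min-max with a blue-to-red colormap; raw
maps are preserved for scoring. The quantitative score `attention_fraction`
is the share of total heatmap mass inside a region mask, with the mask's
area fraction as the chance baseline; a zero-total heatmap scores 0 with an
explicit flag.

The classic CAM formulation (global-average-pooling head) is not separately
implemented; for a GAP head it coincides with Grad-CAM.

## Feature analysis

Features are the 512-unit dense layer's post-LeakyReLU activations (the
2-unit logit layer would make a 3-component PCA degenerate). PCA uses
mean-centered covariance (centering is standard even where a covariance
formula omits it) and reports the top-3 orthonormal components with
descending explained variances.

KNN-Sigma traces leave-one-out k-NN accuracy over k expressed as a
percentage of sample size (grid 1%..100%, step 1%; k = max(1,
round(pct/100 · (n−1)))). The neighborhood is the *extended* k-nearest set:
every point within the k-th-nearest distance, all distance ties included,
so |tau_k| >= k and tau_k is monotone in k. Choices:

* The query point is excluded from its own neighborhood; self-inclusion
  would trivially pin accuracy at 100% for k = 1.
* Majority-vote ties resolve to the lower class index, deterministically;
  the number of tie events is reported.
* The curve summary is the mean accuracy over the grid. Low-k accuracy
  reflects homogeneous concentration (within-class tightness), high-k
  accuracy heterogeneous separation (between-class distinctness).
* Pairwise distances are computed with plain row-wise norms rather than the
  gram-matrix identity: the tie semantics requires exactly tied pairs to
  compare equal, which algebraic rearrangement loses.

## Synthetic test bed

The generator renders schematic 128 x 128 faces: skin ellipse, hair band,
mouth, and two eyes (sclera ellipse, iris disc, eyelid occlusion), with
per-pixel Gaussian noise (sd 0.03 x 255) and per-frame jitter of the eye
parameters (sd 0.01). Frames are i.i.d. given the subject. Ground-truth
region masks and landmark extrema accompany every frame.

Two independent class cues, calibrated at the subject level:

* **sclera redness** — mean red-minus-green over the visible sclera equals
  redness x 255 by construction; alert mean 0.15, drowsy mean higher by
  `effect_size` (default 3) within-class standard deviations (sd 0.08);
* **eyelid aperture** — alert mean 0.82, drowsy lower by the same rule.

Subject means are clipped at ±1.4 within-class sd, so at effect size 3 the
class ranges cannot overlap: every drowsy subject is strictly redder and
more closed-eyed than every alert one, while the empirical standardized
mean difference stays ≈ 3.2 (clipping shrinks the sd by about 6%).

Gender is encoded *only* in the face context (hair band darkness: dark =
male, light = female; a neutral band when the confound is off), orthogonal
to class by construction (alternating within class). This makes the
directional claim "gender is recoverable from the face but not from the
eyes" true by design, and the package's gender-classification experiment
reproduces it (face AUC ≈ 1.0 vs eye AUC ≈ 0.6 at desk scale).

Because both cues are independently switchable, the attention-localization
experiment isolates the redness cue (aperture effect 0): when the class
signal lives only in sclera color, predicted-class Grad-CAM mass
concentrates on the sclera well above its area baseline (≈ 85% of test
frames at desk scale). With both cues active the drowsy-class attention
shifts to the eyelid-occluded region — the closed-eye cue — which is
geometrically disjoint from the visible sclera; this is a correct
attribution of a different planted signal, not a failure of localization,
and is why the localization experiment controls the cue.

**What passing these tests does not show.** The generator is schematic:
no pose, illumination, occlusion, glasses, facial hair, race or camera
variation, no temporal blink dynamics, and a gender cue far cruder than
real facial dimorphism. Synthetic results validate the *machinery*
(preprocessing, optimization, attribution, feature diagnostics) and the
*directions* of the study's findings, not real-world accuracy figures;
accuracies near 1.0 on this bed say nothing about performance on real
video data.

## Problem sizes used in the test suite

End-to-end experiments run at 40 subjects x 12 frames, 2,000 SGD steps,
batch 4 (eye model) — chosen so a full four-iteration experiment trains in
a few minutes on one CPU core while leaving the subject-level splits
non-trivial. The gender comparison uses 600 steps (both models separate the
planted cue, or fail to, well before that). KNN-Sigma oracle checks run at
n ≤ 60, d ≤ 8 with coarsely rounded coordinates to force distance ties.

## Known limitations

* Batch statistics make training-mode outputs batch-composition dependent
  (inherent to batch normalization); inference uses running statistics.
* The KNN-Sigma curve costs O(n² log n + n·k_distinct·n); fine for feature
  sets up to a few thousand frames, not tuned beyond that.
* The numpy network trains small models briskly but is no general deep
  learning stack: fixed layer menu, no GPU, no data augmentation.
* ROC/AUC use scikit-learn's threshold sweep; AUC equals the concordant-
  pair (Mann-Whitney) statistic, which the tests assert on random score
  sets.
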