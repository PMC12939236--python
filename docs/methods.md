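# Methods

## Model

The classifier is a hybrid of local convolutional feature extraction and
global token mixing.  A backbone CNN maps a single-channel slice to spatial
feature maps; adaptive average pooling to a fixed 4×4 grid followed by a
learnable 1×1 convolution yields 16 tokens of dimension D = 256, ordered
row-major so token i sits at grid cell (i // 4, i mod 4) — the convention
every importance map in the package relies on.  One transformer block
(4-head scaled dot-product self-attention, then a position-wise
feed-forward net with expansion ratio 4) refines the tokens through plain
residual additions; there is deliberately **no layer normalization inside
the block**, because the residual equations of the design are
`T1 = T0 + MSA(T0)`, `T2 = T1 + FFN(T1)` and nothing else — normalization
appears only in the classification head (LayerNorm, then a single linear
map of the mean-pooled token).  This also makes the residual-identity
property exact: zeroing the attention output projection and the second FFN
layer reduces the block to the identity on `T0`.

Two backbones are provided.  `resnet18` is the standard 18-layer residual
network without its classification head (total stride 32; a 224² input
yields 512×7×7 maps; 11,176,512 parameters).  Pretrained weights are not
bundled, so `pretrained=True` raises; the architecture still serves
shape/parameter contracts and full-scale experiments from random init.
`tiny_cnn` (three stride-2 conv-ReLU blocks, 16/32/64 channels) is the
CPU-scale backbone used throughout the synthetic study.  Single-channel
inputs are replicated across channels when the backbone expects three.
The transformer add-on (≈0.8 M parameters) is small next to ResNet-18
(≈7%), which is asserted in the tests.

Open choices resolved here: FFN expansion 4 (standard practice,
configurable); positional embeddings initialized N(0, 0.02²); Q/K/V as
three separate linear maps; dropout defaults to 0; argmax ties break toward
the lower (less severe) stage.

## Objective

`L = L_CE + 0.3·L_ord + 0.2·L_cons`, all terms batch means.

* `L_ord = (Σ_c c·softmax(z)_c − y)²` — the squared error of the expected
  stage index.  A point mass on class k costs exactly (k − y)², so a
  3-stage miss is 9× an adjacent miss; the loss is invariant to logit
  shifts.
* `L_cons = ‖softmax(z) − softmax(z̃)‖²` between a slice and its
  horizontally flipped view.  No stop-gradient: both views receive
  gradients, matching the plain MSE formulation.
* CE and the ordinal term are computed on the original view only; the
  perturbed view enters solely through the consistency term.

## Training protocol

Stratified K-fold (default 5) assignment happens on original records only
and *before* augmentation; augmented records inherit their parent's fold,
and `train_fold` refuses to start if any lineage crosses the
train/validation boundary.  Subject-grouped splitting
(`group_by_subject=True`, via stratified group K-fold) is available; the
phantom generator assigns one subject per image by default so the grouping
machinery is exercisable.

Training augmentation: rotation uniform in ±10°, horizontal flip p = 0.5,
random resized crop with scale in [0.8, 1.0] — mild, anatomy-preserving
ranges.  Validation applies resizing and z-score normalization only (the
normalizer is fit on the training fold).  Optimization is AdamW
(lr 3·10⁻⁴, weight decay 10⁻⁴, batch 8) for up to 100 epochs with early
stopping on validation accuracy (patience 10; per-fold seeds are
`seed + fold`).  The returned weights are those of the **first** epoch
attaining the best validation accuracy (strict improvement), so runs that
saturate early return early-epoch weights.  The `mixed_precision` flag is
accepted but the CPU path always computes in full precision.

## Synthetic phantom generator

The generator emulates the essential structure of centered, skull-stripped
2D slices: a bright brain ellipse filling most of the frame (semi-axes
0.46/0.48 of the image — frame-filling matters: with a small brain, the
z-scored empty background dominates the corner tokens' embedding norms and
corrupts the interpretability substrate), a dark central ventricle, a
bright cortical band, and additive Gaussian noise (σ = 0.05) clipped to
[0, 1].  Two modes:

* `discriminative_quadrant="center"` (default): the ventricle area grows
  and the cortical band thins strictly with stage — the classic
  ventricular-enlargement / cortical-thinning pattern.
* a named quadrant: the central anatomy is held at its baseline and the
  stage signal is confined to an "atrophy" patch in that quadrant (radius
  (0.06 + 0.08·stage/3)·size, darkening 0.2·(1+stage)), giving
  interpretability analyses a ground-truth discriminative region.

Default class counts (200, 175, 154, 102) keep the 12800 : 11200 : 9856 :
6528 proportions of the public slice dataset this generator stands in for,
scaled by 1/64; a balanced mode is a parameter away, since the source data
is described both ways.  A 64-pixel `fast_profile` with proportionally
scaled geometry backs the CPU study.

What the phantoms do **not** emulate: anatomical variability between
subjects, partial-volume and bias-field effects, slice-position variation,
and any texture beyond Gaussian noise.  Passing tests therefore demonstrate
that the pipeline's machinery (losses, splitting, attention, importance
maps) behaves as designed on data with a known ground truth — not that the
model reaches any particular accuracy on real MRI.

## Desk-scale study and what it shows

The acceptance study trains the tiny backbone on 600 quadrant-mode phantoms
(150 per stage, 64 px, one stratified fold of five, 5 epochs, ≈1 min on one
CPU).  Under these conditions the model reaches perfect or near-perfect
validation accuracy, commits no maximal-distance (Δ = 3) ordinal errors,
and the full objective's mean absolute ordinal error is no worse than a
CE-only run under identical conditions.  Mean token importance inside the
discriminative quadrant exceeds the outside mean (localization ratio ≈ 1.3
at the default seed), and the stage-3 class-mean map peaks at the patch
cell.  The top-4 concentration score correlates positively with stage at
the default study seed (Spearman ρ ≈ +0.87); across other seeds the
*direction* of this trend is unstable at desk scale — 5-epoch tiny models
are barely past convergence — so only the localization property, which is
stable across seeds, should be read as a robust finding of the synthetic
study.

## Numerical choices

* All computation in float64; the autograd engine's primitives are checked
  against central finite differences at 1e-5–1e-6 tolerance.
* Softmax and log-softmax use max-subtraction; CE clips probabilities at
  1e-12 only in the (non-differentiated) validation-loss bookkeeping.
* Importance grids: per-slice min-max normalization; all-equal norms map to
  all-ones by convention.  Concentration scores require positive total norm
  and raise otherwise.  Spearman correlation is used for the stage trend
  because only monotonicity is claimed.
* Confusion rows with zero support normalize to all-zero rows; classes
  absent from the ground truth are dropped from macro curve averages with a
  warning.  Multiclass precision/recall/F1/AUROC/AUPR are macro one-vs-rest
  (micro via flag); fold tables append mean and sample std (ddof = 1).
* Ordinal Δ percentages are reported on both bases (all predictions, and
  errors only) since either convention is defensible; overestimation means
  predicting a *more* advanced stage (ŷ − y > 0).

## Limitations

* No pretrained backbone weights; full-scale ResNet-18 training in numpy is
  possible but slow, and is not part of the test surface.
* Slice-level only: no subject-level aggregation of predictions.
* The interpretability mechanism is embedding-norm based by design; no
  gradient saliency, and no claim that norm importance equals causal
  relevance.
* Single transformer layer and a fixed 4×4 token grid; multi-layer stacks
  and finer grids are out of scope.
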