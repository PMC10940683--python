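# Methods

## The attention operator

The core of the package is a spatial–channel attention operator for CNN
feature maps, built around *strip pooling*: pooling an entire row (or column)
of a C×H×W feature map into one value per channel, so that each channel
yields four 1-D descriptors —

    aʰ_c(h) = (1/W) Σ_i x_c(h, i)        (average over each row)
    aʷ_c(w) = (1/H) Σ_j x_c(j, w)        (average over each column)
    mʰ_c(h) = max_i x_c(h, i)            (max over each row)
    mʷ_c(w) = max_j x_c(j, w)            (max over each column)

The averages capture long-range context along an axis; the maxima keep
locally salient responses that averaging washes out.  The operator then:

1. splices the pairs into **a** = [aʰ, (aʷ)ᵀ] and **m** = [mʰ, (mʷ)ᵀ], each of
   length H+W, and stacks both into one length-2(H+W) sequence;
2. squeezes it through a shared 1×1 convolution (C → max(C//r, mid_min)
   channels), batch norm and hard-swish;
3. splits the result back at H+W, restores each half to C channels with its
   own 1×1 convolution + batch norm, transposing the second half, giving a
   column embedding h_a ∈ R^(C×(H+W)×1) and a row embedding
   h_m ∈ R^(C×1×(H+W));
4. multiplies them per channel into an embedding map
   h_am = h_a·h_m ∈ R^(C×(H+W)×(H+W)) whose four quadrants carry all four
   axis interactions (avg×avg, avg×max, max×avg, max×max) — each channel
   slice has rank ≤ 1 by construction;
5. downsamples h_am with a 3×3, stride-2, padding-1 convolution and a
   sigmoid into a gate g ∈ (0,1)^(C×H×W), and returns y = x ⊙ g.

Coordinate Attention (CA), the ancestor design and the built-in baseline,
uses average strips only and factorizes its gate as g[c,i,j] = g_h[c,i]·g_w[c,j];
the embedding-map operator is strictly more expressive (its gate need not
factorize) at a few extra 1×1/depthwise weights.

Ablation switches `pool_mode = AP_AP | MP_MP` replace both branches by
average or by max pooling; on constant inputs all three modes coincide
exactly (avg = max on constants), which the tests exploit as an oracle.

### Choices the design left open

* **Reduction ratio r.** Default r = 32 with a mid-channel floor of 8 — the
  squeeze-excitation/CA convention this operator family descends from.
* **Downsampling convolution structure.** Only kernel/stride/padding are
  dictated by the shape algebra; the channel structure is free.  Default is
  depthwise (groups = C), which keeps the operator budget-neutral (a full
  C→C 3×3 at C = 512 alone would cost ~2.4M parameters); `full` and
  `grouped(n)` are selectable.
* **Non-square maps.** The stride-2 downsampling maps (H+W)² to H×W exactly
  only when H = W.  Default `require_square` raises a clear error naming the
  alternative; `bilinear` resizes the gate with differentiable interpolation
  matrices.
* **Bias/normalization conventions.** 1×1 convolutions are bias-free (each
  is followed by batch norm, eps 1e-5, momentum 0.1); the downsampling
  convolution carries a bias.  Batch statistics in training, running
  statistics at inference.  Kaiming-uniform initialization, seeded.

## Numerical core

All models run on a small reverse-mode autodiff engine over NumPy arrays
(`autodiff.py`, `nn.py`): broadcasting arithmetic, matmul, elementwise
nonlinearities, axis reductions, grouped 2-D convolution via im2col, max
pooling, batch norm, AdamW and softmax cross-entropy.  Max-pool and max
reductions route gradients to the first argmax; every primitive is verified
against central finite differences in float64.  Forward compute uses BLAS
matmuls, which makes single-CPU training of the small pipeline model and
single forwards of the full backbones practical.

## Backbones and budget accounting

ResNet-34, MobileNetV2 (width 1.0) and EfficientNet-B0 are reproduced with
the standard channel/stage structure; with 1000-class heads the parameter
counts match the reference implementations exactly (21,797,672 / 3,504,872 /
5,288,548), and with 3-class heads they match the published 2.23M and 4.01M
figures this package targets.  Dropout and stochastic depth are omitted
(they carry no parameters and the package never trains the large backbones).

MAC counting instruments an actual forward pass.  Two conventions are
exposed: `conv_linear_only` (weight MACs of convolutions and linear layers)
and the default `profiler` convention, which additionally counts one op per
conv/linear output element and the elementwise work of batch norm
(2/element), activations (1/element) and pooling (1/element).  The default
reproduces the published per-backbone figures at 256×256 (4.8042 G / 0.4261 G
/ 0.5404 G) within 1%; conv-only undercounts the two mobile architectures by
7–8% because elementwise work is a larger share of their budget.

Attention injection defaults to `final_stage`: one operator after the last
feature *block* — C = 512 for ResNet-34; C = 320 for MobileNetV2 and
EfficientNet-B0, i.e. before the 1×1 head convolution, which belongs to the
classifier head.  At that site the operator adds ≤ 0.7% parameters and
≤ 0.11% MACs to every backbone (the budget-neutrality property the tests
assert).  Placing it after the 1280-channel head conv instead would add
~7.7% parameters to MobileNetV2 for no extra spatial context; `every_stage`
and `per_block` placements remain available for budget exploration.

## Preprocessing

* **Optical density.** OD = −log10(I/255), intensities clipped at 1.
* **Stain basis.** A 2-atom nonnegative sparse dictionary (sklearn
  MiniBatchDictionaryLearning, coordinate-descent, α = 0.1, ≤ 10,000 tissue
  pixels with ‖OD‖ > 0.15, seeded) learned per image; columns unit-normalized
  and ordered hematoxylin first (larger red-OD component).  Images with
  < 1000 tissue pixels raise `InsufficientTissueError`; nearly parallel or
  collapsed atoms raise `DegenerateStainError` instead of returning garbage.
* **Concentrations.** With two stains, nonnegative least squares has a
  closed-form case analysis (unconstrained 2×2 solve; clamp a negative
  coordinate and refit the other), fully vectorized over pixels.
* **Normalization.** Concentrations are fitted under the source basis, each
  stain channel rescaled so its 99th percentile matches the reference
  image's, and the image recomposed under the reference basis.  The
  reference is the first image in the dataset with sufficient tissue
  (configurable); a per-fold reference would multiply cost for no practical
  gain, since only global color statistics cross the split.
* **Cropping and QC.** Three 256-px crops per normalized scan at seeded
  uniform offsets.  A pixel is *blank* when all channels ≥ 220; a patch is
  removed when blank pixels exceed 75% of its area (strictly more than —
  exactly 75% is kept).
* **Folds.** Stratified 5-fold assignment at case level (every patch
  inherits its case's fold), per-grade fold sizes differing by at most one
  case; any case appearing on both sides of a split aborts the run.

## The synthetic generator

The study material the pipeline targets — per-case sets of 1665×1393 px
HE-stained scans with a low/intermediate/high grade label — is private, so
the generator emulates its pipeline-relevant features: nuclei are
Gaussian-profile blobs (radius 6 px) in the hematoxylin concentration
channel at 20 / 45 / 90 blobs per 256² tile for the three grades (Poisson
counts; strict ordering is what makes the labels learnable); stroma is a
smooth random field in the eosin channel, clipped so roughly a third of the
tissue is stroma-free and attenuated by exp(−2·hema) under nuclei — nuclei
displace cytoplasm, and without stain-pure pixels the two stain directions
would not be identifiable from the data at all.  Per-image stain-vector
jitter (±5% lognormal) reproduces the color variation normalization must
remove; an optional rectangular paper-white region (default 10% of the
area) exercises the blank-patch filter.  Grades differ *only* in texture
statistics: there is no growth-pattern morphology, no scanner noise, no
compression artifacts.  Passing tests therefore demonstrate that the
pipeline's stages compose and that the operator trains — not clinical
performance on real tissue.

## Training and evaluation

The published recipe is implemented as the default configuration: AdamW
(lr 1e-4, weight decay 1e-2), batch 16, 256-px inputs, cross-entropy,
200 epochs with a linear warm-up across the first epoch and cosine
annealing to exactly zero at the last.  `lr_at_epoch` accepts fractional
epochs; the trainer applies it per iteration.

Metrics are computed from the confusion matrix by the package itself
(accuracy; per-class precision/recall/F1 with macro and support-weighted
averaging; Cohen's kappa; the K-category Matthews correlation) and verified
against scikit-learn to 1e-10 in the tests; AUC is scikit-learn's
one-vs-rest ROC-AUC on softmax scores, macro-averaged by default with the
weighted variant also reported (the published tables do not say which).
A zero-support class contributes zeros with a logged warning.  Fold results
aggregate as mean ± sample standard deviation (ddof = 1).  Model selection
is final-epoch weights — no early stopping.

### The smoke experiment

The end-to-end check trains the three-conv + attention tiny CNN under
case-level 5-fold CV on the generator's default output (5 cases/grade,
2 scans/case, 3 crops each, ~75 patches after QC).  Its configuration is
scaled to that regime: patches block-averaged to 128 px (4× downscaling
would blur the ~6 px nuclei the labels depend on), batch 8 (a training fold
holds only ~60 patches), lr 3e-3 for 10 epochs (a tiny model trained from
scratch on a short schedule, as opposed to the 200-epoch fine-tuning
default).  Under these conditions cross-validated accuracy lands around
0.75–0.82 over seeds against a 1/3 chance level.  Runtime is a few minutes
on one CPU; the full experiment is re-run from scratch by
`scripts/acceptance.py`.

## Grad-CAM

Gradients of the chosen class logit are taken at a named stage output
(default: the last stage before pooling, i.e. after the attention block),
averaged per channel into weights, combined into a rectified weighted sum,
bilinearly upsampled and min–max normalized; an all-constant map normalizes
to zero rather than NaN.  On the synthetic fixture, activation for the
high-grade class concentrates in the quadrant holding the nuclei.

## Known limitations

* The generator makes no claim of histological realism; results on it bound
  nothing about real lung adenocarcinoma slides.
* The published accuracy tables stem from a private dataset and GPU-scale
  training and are out of reach by design; only compute budgets, operator
  algebra and pipeline mechanics are reproduced.
* The attention insertion sites behind the published +0.08M/+0.51M overhead
  rows are not derivable from the text; this package fixes a budget-neutral
  default instead.
* Batch-norm layers see small batches in the smoke regime; running
  statistics are correspondingly noisy.
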