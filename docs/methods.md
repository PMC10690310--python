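# Methods

## The model

`slivit` treats a volumetric scan — an OCT B-scan volume, an echocardiogram
frame stack, an MRI slice series — as an ordered set of N grayscale slices
and factorizes the 3D problem into "2D feature extraction, then cross-slice
integration":

1. **Standardization.** Each slice is (optionally) contrast-stretched
   between its 2nd and 98th intensity percentiles, bilinearly resized to the
   backbone's input side, replicated to three channels, and normalized with
   the fixed natural-image channel statistics (means 0.485/0.456/0.406, stds
   0.229/0.224/0.225) so that weights transferred from natural-image
   pretraining stay calibrated.
2. **Tiling.** The N standardized slices are concatenated vertically into a
   single elongated image of height N·side. One backbone pass over this
   image costs the same as N independent slice passes but amortizes
   per-call overhead and keeps the model a plain 2D network.
3. **Backbone.** A ConvNeXt feature extractor (stem: 4×4 convolution with
   stride 4 + layer norm; stages of blocks: 7×7 depthwise convolution →
   layer norm → 1×1 expansion ×4 → GELU → 1×1 projection, with a learnable
   per-channel layer scale initialized at 1e-6 and a residual connection;
   between stages: layer norm + 2×2 stride-2 convolution). The full
   tiny-variant geometry is (3,3,9,3) blocks at widths (96,192,384,768) with
   total downsampling 32, so a 256-px slice yields an 8×8 map with F=768
   channels; an N-slice tiled image yields an (N·8)×8×768 map.
4. **Tokenization.** The (N·8)×8 output is split into N per-slice 8×8×F
   maps. Each is flattened and sent through one shared affine layer to a
   token of width `token_dim`; a trainable positional vector, initialized to
   the constant value i for slice i (0-based), is added, and a trainable
   class token (truncated-normal, 0.02) is prepended.
5. **Integration.** A 5-layer pre-norm transformer encoder (12 heads at
   width 768, MLP ratio 4, GELU, no dropout) processes the N+1 tokens. The
   encoded class token passes through a final affine head: one logit for
   binary classification, one unbounded real for regression, k logits for
   k-way classification (used in 2D pretraining with k=4, where the head
   sits on a globally average-pooled backbone feature instead).

Slice count N is free at run time: positional vectors are allocated up to a
configured maximum and sliced. Tiling is used verbatim, without padding
between slices, so 7×7 depthwise kernels mix a few rows across slice
boundaries; the stem-only configuration (zero blocks, so every spatial
kernel equals its stride) is provided as an exactness oracle for which
tiled and per-slice processing agree block-for-block.

Two observations about the positional initialization are worth recording.
The description "initialize the positional embedding as the slice number"
and "initialize the tokenizer bias as the feature-map number" are one
mechanism here: a single shared tokenizer cannot carry per-slice biases, so
the per-position additive vector carries the index. And because a vector
with all components equal is pure channel-mean, layer normalization removes
it exactly: at initialization the encoder is effectively
permutation-equivariant, and order sensitivity can only emerge through
training of the positional vectors. This is consistent with the observed
robustness of the trained models to frame shuffling.

## Numerical choices

- **Engine.** The network runs on a small reverse-mode autodiff engine over
  float32 numpy arrays (`slivit.nn`), written for this package: channels-last
  layout, pointwise convolutions as BLAS matrix products, stride-equals-kernel
  convolutions as patch reshapes, and a shift-and-accumulate depthwise
  convolution. GELU uses its sigmoid form x·σ(1.702x).
- **Initialization.** Linear and convolution weights use truncated-normal
  draws scaled by 1/√fan_in. A fixed small std (the 768-width convention)
  attenuates activations severely at reduced widths and stalls optimization;
  fan-in scaling behaves uniformly across the width range used here.
- **Optimizer.** Decoupled-weight-decay adaptive moments with betas
  (0.9, 0.99), eps 1e-5, weight decay 0.01 — the defaults of the training
  framework the protocol names rendered numerically, so there is no
  framework-by-reference dependency.
- **One-cycle schedule.** Cosine warmup from base_lr/25 to base_lr over the
  first 25% of the planned steps, cosine annealing to base_lr/1e4; the
  first-moment factor cycles 0.95 → 0.85 → 0.95 inversely. The cycle length
  is `max_epochs` × steps-per-epoch; early stopping may end training before
  the anneal completes.
- **Early stopping and selection.** Validation loss (the task loss, not the
  task metric) is evaluated each epoch; training stops after 5 epochs
  without improvement, and the weights from the best-validation epoch are
  restored. Batches hold 4 volumes; all volumes in a batch must share N.
- **Learning-rate finder.** ~100 minibatch steps with lr growing
  exponentially from 1e-7 to 10, loss exponentially smoothed (0.98,
  debiased), aborting once the smoothed loss exceeds 4× its running
  minimum. The suggestion is the lr at the steepest negative windowed slope
  of the smoothed curve (8-step window, 10-step burn-in), divided by 10 and
  clipped to [1e-6, 1e-1].
- **Augmentation.** One transform per volume, applied identically to every
  slice: horizontal flip (p=0.5) and random resized crop (scale 0.08–1.0,
  aspect 3/4–4/3). Evaluation-time preprocessing is deterministic. In the
  synthetic experiments only flips are used: the synthetic targets are
  areas and intensity fractions, which crops rescale, so cropping would
  inject label noise rather than invariance.
- **Splits.** Train size is floor(f_train·n); when validation and test
  fractions are equal the remainder is halved with the floor going to
  validation. This one rule reproduces 483/104/104 from 691 at 70/15/15,
  5972/1991/1991 from 9954 at 60/20/20, and floor(0.25·7465)=1866.
- **Frame-count standardization.** Videos are subsampled to k equally spaced
  frames at indices round(i·(N−1)/(k−1)) (endpoints included; indices repeat
  when N<k — how the original videos shorter than the target length were
  expanded is not documented, so repetition at the rounded positions is this
  package's choice). Slice decimation keeps even indices (so 97 → 49) after
  an optional depth-only Gaussian anti-aliasing filter (σ = 1 slice,
  truncated at 2σ, reflective boundary — σ=1 is the standard choice for
  decimation by two).
- **Statistics.** Bootstrap with B=1000 resamples of the n test predictions
  (with replacement); degenerate resamples (single-class for AUC,
  zero-variance for R²) are redrawn so exactly B scores remain. The 90% CI
  is the 50th and 950th ranked scores (1-based ranks r and B−r with
  r=⌈B(1−level)/2⌉). Two models evaluated with the same seed on the same
  test set receive identical resample streams, so model comparison is a
  two-sided one-sample t-test on the paired per-resample score differences,
  with Bonferroni-corrected significance at 1e-3. ROC AUC uses the
  Mann–Whitney tie convention (half credit); PR AUC is step-wise average
  precision.

## Synthetic data

The real datasets behind this line of work are private or download-gated,
so a generator module reproduces their statistical task structure at desk
scale — the defaults are 64×64 frames, 16 slices, a few hundred volumes,
noise σ=0.05, all drawn from one named generator per dataset (bitwise
reproducible from its parameter set and seed; anti-aliased analytic masks, no mesh
rendering):

- **Four-class 2D images** (backbone pretraining): horizontal bands, bright
  blobs, speckle, smooth gradients — linearly separable textures with
  additive noise, balanced labels.
- **Structural-biomarker volumes** (binary): a bright lesion spanning
  n_slices ∈ {3…12} consecutive slices with per-slice disc radius
  base_radius·u/√n_slices (u ~ U(0.75, 1.25), ±10% per-slice jitter). The
  label is defined as total lesion voxel count > 1256 (≈ the count at u=1
  with base radius 20), so the scale u carries the label while the slice
  extent does not. Because area anti-correlates with extent, a single
  slice's presence or area leaves the label ambiguous: a logistic
  regression on the middle slice's raw pixels reaches only ~0.6–0.65 ROC
  AUC, while the full label is exactly recoverable from 3D aggregation.
  Labels come out ≈ balanced.
- **Dynamic videos** (regression in [0,1]): a dark chamber on bright tissue
  whose area oscillates with a random period (10–14 frames) and phase; the
  target is the fractional area change (A_max − A_min)/A_max of the
  generated frame sequence — an ejection-fraction analog. Random phase
  makes any single frame weakly informative (ridge regression on one frame:
  R² < 0.5, typically ≈ 0).
- **Textured slabs** (regression): a stored fraction f ~ U(0.02, 0.5) of
  voxels drawn from a bright intensity mode (0.8 ± 0.05) against tissue
  (0.3 ± 0.05), with f varying slice-to-slice (σ=0.03) around the volume
  mean — a fat-fraction analog where multi-slice aggregation reduces error.

What these volumes deliberately do not model: speckle physics, k-space
artifacts, anatomy, registration error, scanner intensity drift. Passing
the synthetic benchmarks demonstrates that the architecture aggregates
cross-slice information end-to-end under the stated training protocol; it
does not certify clinical performance.

Because the synthetic volumes are generated already intensity-calibrated,
the experiment drivers disable per-slice contrast stretching: stretching
each slice to its own percentile range erases exactly the cross-slice
intensity comparisons (total lesion volume, bright-voxel fraction) that the
targets are built on, while on real scanner output it serves as
normalization. This is an experiment-configuration choice; the general
pipeline default keeps the stretch.

## Desk-scale experiment configuration

The full tiny backbone trains in hours on accelerator hardware; on one CPU
core the experiments instead use the `compact_config` preset: 64-px slices,
stages (0, 2) at widths (12, 24) (downsampling 8, preserving the 8×8
per-slice grid), token width 32, 4 heads, depth 5 — ~160k parameters. At a
few hundred training volumes this narrow model also regularizes much better
than wider variants. Benchmark runs use 300 train / 40 validation / 100
test volumes of 16×64×64 for classification, base learning rate 1e-3 fixed
by a small sweep (the automatic finder assumes a loss curve that descends
then diverges and is unreliable on this task's plateau-shaped early loss),
up to 25 epochs
with patience 5, horizontal-flip augmentation, and batch size 4; the
fraction sweep and permutation study run smaller configurations of the same
shape from random initialization. The benchmark runs follow the transfer
protocol — the backbone is first pretrained on the synthetic 4-class 2D
images, then fine-tuned end to end. Training at this scale is stochastic:
a seed occasionally makes a noise-level validation improvement during the
low-lr warmup and then triggers patience before the loss plateau breaks
(~a fifth to a third of seeds). Experiments therefore aggregate over
training seeds — majority over three seeds in the test suite, median of
three in the acceptance script — rather than reporting a single run.
Problem sizes are stated with each experiment in the acceptance script.

## Known limitations

- Single-threaded CPU training bounds feasible model width and data volume;
  the full 256-px tiny-variant configuration is exercised for architecture
  contracts (shapes, tiling equivalence, transfer round-trips) but not
  trained to convergence here.
- The bootstrap CI uses the quoted rank convention (50th/950th of 1000),
  which is asymmetric by one rank from the textbook percentile interval;
  empirical coverage at these sizes is within the tested ±5% band.
- Batches require equal N (datasets standardize frame counts upstream);
  padding/masking of ragged volumes is out of scope.
- The per-slice (not per-volume) contrast stretch and the repetition rule
  for short videos are this package's choices where the protocol is silent.
- Below roughly 100 training volumes the fixed-patience protocol becomes
  unreliable (the warmup plateau outlasts patience more often than not), so
  the smallest fraction-sweep subsets can under-converge; the sweep reports
  whatever the protocol produces.
- The paired bootstrap t-test inherits the quoted convention of treating
  the B resample differences as samples (standard error sd/√B). This makes
  it extremely sensitive: any two separately trained networks whose test
  metrics differ by more than a few thousandths are declared significantly
  different, so it resolves model-versus-model differences but cannot be
  read as "the models are interchangeable" — the permutation study's
  rank-based summary is the right lens for that question.
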