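# Methods

This note documents the model, the numerical choices, the synthetic data
the package is tested on, and the limits of what those tests show.

## Problem and model

The task is binary semantic segmentation of 2-D micrographs of cells:
each pixel is foreground (cell) or background.  The architecture is a
U-shaped encoder-decoder in which the plain skip connections are replaced
by a three-part fusion path.  The motivation is the *semantic gap* of
U-Net skips: shallow encoder features and deep decoder features have
different distributions, and naive concatenation fuses them poorly,
especially where cell/background boundaries are soft.

**Backbone.**  Encoder stage *i* (1-based) applies two 3x3 same-padded
convolutions, each followed by batch normalisation and ReLU, yielding
`base_channels * 2^(i-1)` channels at `1/2^(i-1)` of the input
resolution; 2x2 max pooling links stages, and a bottleneck block one
level below the deepest stage doubles channels once more.  Same padding
(instead of the original valid convolutions) keeps the skip and decoder
grids aligned with no cropping.  The decoder mirrors the encoder with
2x2 stride-2 transposed convolutions (a nearest-neighbour + 1x1
convolution alternative is selectable), and a 1x1 convolution head emits
per-pixel scores: sigmoid for one foreground class, channel softmax for
two or more.  Input sizes must be divisible by `2^depth` (and by the
patch size when cross-fusion is enabled); violations raise errors naming
the required divisor.

**Tensor low-rank context.**  Per encoder stage, context is summarised
as 3L rank-1 vectors: for each direction d in {height, width, channel},
L independent feature generators apply global average pooling over the
collapsed axes, a single-channel 1-D convolution (kernel 3,
same-padded — the kernel size is our choice), and a sigmoid that
rescales outputs into [0, 1].  Distinct generators have distinct
parameters so their outputs carry distinct context fragments.  The
vectors are never expanded into outer-product tensors; cost is
O(L(H+W+C)) per stage.

**Channel cross-fusion.**  Stage features are re-expressed as token
sequences by patch embedding with patch edge `P_s / 2^(i-1)`, which
forces the same token count n at every stage; a learned linear map sends
each flattened patch to a shared `embed_dim`-wide token.  The four
(generally `depth`) scales are concatenated along the token axis into a
4n-token sequence.  Attention is computed over the *channel* axis: with
queries `Q = T_{d,i} W_Q` from one stage and keys/values
`K = T_{d,sum} W_K`, `V = T_{d,sum} W_V` from the concatenation, the
score matrix is `embed_dim x embed_dim`.  Two shape decisions were
genuinely open and are resolved as follows:

* the channel product `Q^T K` needs matching token counts, so the four
  scale blocks of K are summed before the product
  (`S = Q^T sum_i K_i`) — equivalent to tiling the queries across
  scales;
* the attended values `V W^T` carry 4n tokens; the four scale blocks are
  averaged to return to the n-token query layout.

Scores are instance-normalised (zero mean, unit variance over the score
matrix) before the softmax over the key-channel axis; this replaces the
usual `1/sqrt(d_k)` temperature, which the attention definition omits.
Each of the N heads owns its `W_Q, W_K, W_V` triple per direction
(shared across stages), head outputs are arithmetically averaged, and
the per-stage fusion is `O_i = sum_d [NCA_{d,i} + LP(Q_{d,i} +
NCA_{d,i})]` where `LP` is a shared two-layer perceptron (hidden width
4x embed_dim, GELU) and `Q_{d,i}` is the head-averaged query.  Tokens
are mapped back to a spatial map by a learned per-stage un-embedding.
No positional encodings are used.

When low-rank context is enabled, each rank-1 vector is averaged over
the token's span along its axis (height vectors per token row, width
vectors per token column, channel vectors per image) and scaled into the
embedding by a learned per-vector direction embedding, added to the
patch tokens of its direction.  This keeps the projection size-agnostic
and exactly linear in L.

**Feature connection.**  The fused encoder output O_i is aligned to the
decoder feature D_i (nearest-neighbour upsampling by the integer scale
factor plus a 3x3 convolution; unit factor in the standard wiring), both
are globally average-pooled per channel and passed through one linear
layer each (channels -> channels, no hidden layer), and the sigmoid of
the summed outputs gates O_i channel-wise; the gated O_i is concatenated
with D_i.  An alternative reading — adding the gate to O_i instead of
multiplying — is selectable (`fc_mode="add"`) for comparison.  With the
gate saturated at 1 the block degenerates to plain U-Net concatenation.

**Variants.**  `baseline` (plain U-Net), `ccf`, `fc`, `ccf_fc`,
`lr_ccf_fc` wire the above modules in the combinations their names
state; a variant constructs only the parameters it uses, so the baseline
carries no attention/gate/context weights and parameter counts increase
strictly as modules are added.

## Loss and metrics

Training minimises `L = alpha * WCE + (1 - alpha) * Dice` with
`WCE = -mean(beta p log p_hat + (1-p) log(1-p_hat))` (predictions
clamped to `[eps, 1-eps]`) and the soft Dice loss
`1 - (2 sum(p_hat p) + eps) / (sum p_hat + sum p + eps)`.  Defaults
alpha=0.5, beta=1, eps=1e-6: alpha and beta are not fixed by the method
definition, so they are exposed in `LossConfig` and logged with every
run.  beta multiplies only the foreground term, countering class
imbalance.  The soft (probability-valued) Dice is used for training;
evaluation uses hard counts.

Evaluation reports, in percent: Dice `2TP/(2TP+FP+FN)`, IoU
`TP/(TP+FP+FN)`, precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, from
pixel confusion counts pooled over a split (micro average; per-image
macro averaging is available).  The IoU is the single-foreground-class
ratio, not a mean over classes.  Conventions: two empty masks score 100
on the overlap metrics; an empty precision/recall denominator yields NaN
and is excluded from macro averages.  Dice is identically the harmonic
mean of precision and recall, a property the tests exercise.

## Synthetic data

Real reproductive-cell micrographs are clinical data and rarely
shareable, so the corpus generator stands in for them: cells are
anti-aliased ellipses (radius 5-14 px by default, eccentricity up to
0.2) whose brightness (0.30-0.50 above a ~0.25 background) falls off
toward the rim to mimic out-of-focus cytoplasm edges; the background
carries low-frequency texture (cubic-interpolated coarse noise); each
new cell touches or overlaps an existing one with probability 0.3;
additive Gaussian noise (sigma = 0.1 of the dynamic range) is applied
last, and intensities are clipped to [0, 1].  Masks are the exact union
of the generating ellipses.  With these defaults foreground occupies
roughly a quarter of pixels, preserving the class imbalance that
motivates the weighted loss.  One top-level seed spawns an independent
stream per image, making corpora bit-reproducible.  Amplitudes were
chosen so a small U-Net does not saturate within a few epochs, leaving
visible headroom between ablation variants.

What this corpus does *not* emulate: real optics (PSF, illumination
gradients), instrument artefacts, debris, time-lapse correlation, and
cell-internal structure.  Passing the end-to-end checks therefore shows
that the architecture, losses and training loop are correct and can
learn this class of imagery — not that the model reaches clinical-grade
accuracy on real micrographs.

## Training protocol

Adam (beta1=0.9, beta2=0.999), constant learning rate 1e-3 (cosine decay
behind a flag, off by default), batch size 4, 40 epochs by default, and
random horizontal/vertical flips as the only augmentation.  Splits are
80/10/10 by manifest.  Non-finite loss aborts with the offending step
named.  Checkpoints are `.npz` weight archives with a JSON sidecar
recording the model configuration.

Determinism: all randomness flows from explicit seeds through
`numpy.random.Generator`; with a fixed seed the implementation is
bit-deterministic on a fixed BLAS configuration, so two identical runs
produce identical histories and metric rows (the test suite exercises
this).

## Numerical choices and scales

* Everything trains in float32; the `cellseg.nn` autodiff engine
  implements hand-written backward passes for convolution (im2col),
  transposed convolution, pooling and batch normalisation, all verified
  against central finite differences.
* Max-pool gradient ties route to the first maximal element;
  `predict_mask` maps probability ties (p = threshold) to foreground.
* He-uniform initialisation for all weights, zero biases; a model seed
  fully determines the initialisation.
* The scaled-down problem sizes used by the tests and the acceptance
  script — 64x64 images, base 16 channels, 15 epochs on 200 training
  images; depth 3 for the single-image overfit check; a 48/12 corpus
  over three seeds for the ablation comparison — were chosen as the
  smallest sizes at which training dynamics are representative while a
  full run stays comfortable on a single CPU.

## Known limitations

* Binary (plus optional 2-class softmax) segmentation only; no instance
  labels, no 3-D volumes, no pretrained weights.
* The channel-attention shape resolution (key block-sum, value
  block-average) is one of several defensible readings of the fusion
  definition; alternatives (e.g. concatenating scales along the channel
  axis) would change parameter shapes but not the module's role.
* Bilinear decoder upsampling is approximated by nearest + 1x1
  convolution when the transposed-convolution path is not used.
* The NumPy engine is single-threaded-BLAS fast, not GPU fast: it is
  sized for corpora of hundreds of small images, not clinical-scale
  training.
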