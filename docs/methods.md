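# Methods

## Model

SVNC-Net is a U-shaped 2D fully-convolutional network for binary
segmentation of axial CT slices. The encoder has four stages of two
convolutions each, with 2×2 max-pooling between stages, followed by a
bottleneck pair; the decoder mirrors the encoder with learnable upsampling
and concatenating skip connections; a 1×1 convolution and a sigmoid yield
per-pixel foreground probabilities on the input grid.

The defining design constraint is the parameter budget: with encoder
widths 32/64/128/256 and a 512-channel bottleneck, the whole network must
round to 1.0 M trainable parameters at one-decimal millions. The operator
choices that satisfy it:

- **Encoder stage 1** uses standard 3×3 convolutions (1→32→32): a depthwise
  filter over a single input channel extracts almost nothing, so the
  separable factorization starts at stage 2 (`separable_from_stage`, default
  2).
- **Stages 2–4 and the bottleneck** use depthwise-separable double blocks in
  MobileNet layout: 3×3 depthwise → BN → ReLU → 1×1 pointwise → BN → ReLU.
  The bottleneck pair dilates its depthwise filters by 2 (default
  `bottleneck_dilation`), widening the receptive field at zero parameter
  cost.
- **Decoder upsampling** is "separable transposed": a depthwise 2×2
  stride-2 transposed convolution followed by a 1×1 pointwise channel
  reduction, each with BN+ReLU. A plain dense 2×2 transposed convolution
  512→256 alone would cost 0.52 M parameters and blow the budget; the
  separable form costs 4·512 + 512·256 kernel weights.
- **Decoder blocks** repeat the operator family of the matching encoder
  stage, so the final stage (→32) is standard convolutions mirroring
  stage 1, and the head is a 1×1 convolution with bias.
- Convolutions feeding a batch norm carry no bias; batch norm has learnable
  affine parameters and exponential running statistics (momentum 0.1, eps
  1e-5; batch variance is the biased estimator throughout).

The reference configuration totals 1,034,785 trainable scalars, inside the
[0.95 M, 1.05 M) window that prints as 1.0 M (round-half-up). The count is
independent of `input_size` and of the padding mode, because every
parameter is kernel-shaped.

### Spatial geometry

Under the default "same" padding, every stage halves the grid exactly and
a 512×512 input reaches the bottleneck at 32×32 (512/2⁴). An alternative
`padding_mode="valid_stage4"` leaves the fourth encoder stage's convolution
pair unpadded, shrinking its grid by 4 before pooling, which puts the
bottleneck at 30×30; zero-padding on the decoder side of each skip
concatenation reconciles the shapes on the way up. Both modes have
identical parameter counts; "same" is the default for its cleaner
round-trip geometry. The network's layer count depends on the counting
convention (convolutions alone vs. convolution+BN+activation triplets), so
no specific "number of layers" is asserted anywhere.

### Cost model

`standard_conv_cost` and `separable_conv_cost` implement the
multiply–accumulate counts D_k²·M·N·D_f² and D_k²·M·D_f² + M·N·D_f², in
exact integer arithmetic; their ratio is algebraically 1/N + 1/D_k²
(`cost_reduction_ratio`), independent of M and D_f, which the property
tests verify to 1e-12 over random specifications.

## Execution engine

No GPU framework is a dependency: the network runs on a small static-graph
engine (`svncnet.nn`) written on NumPy. Each operation (standard,
depthwise, pointwise and depthwise-transposed convolution, batch norm, 2×2
max-pool, concatenation, padding, ReLU, sigmoid) implements a forward and
a reverse-mode backward pass; convolutions are computed as kernel-tap sums
of BLAS channel mixes, which is exact and adequately fast for 3×3 kernels
at desk scale. Backward passes are verified against finite differences in
float64. Arrays are float32, layout (batch, channel, height, width). The
optimizer is Adam (β₁ 0.9, β₂ 0.999, eps 1e-8).

## Loss and schedule

The training loss is the convex combination L = α·L_Dice + (1−α)·L_BCE
with α = 0.5. The Dice term is the soft formulation over probabilities,
1 − (2Σpy + ε)/(Σp + Σy + ε), per sample and batch-averaged, with ε = 1e-6
in numerator and denominator — differentiable, and well defined on empty
masks. BCE is the pixel mean with probabilities clipped to
[1e-7, 1−1e-7]. Analytic gradients with respect to the probabilities feed
the graph's backward pass.

The learning rate follows cosine annealing with warm restarts:
η(T_c) = η_min + ½(η_max − η_min)(1 + cos(π·T_c/T_i)), η_max = 1e-3,
η_min = 1e-5, cycles of 10/20/20 epochs (50 total), so restarts occur at
epochs 0, 10 and 30. The schedule steps per epoch by default; `lr_at`
accepts fractional T_c for per-iteration stepping. No weight decay or
gradient clipping is applied.

## Data pipeline

Volumes are NIfTI, loaded with nibabel and transposed to (z, y, x).
Intensities are min–max normalized to [0, 1] per volume, with an optional
HU window clip beforehand (none by default). Each volume is decomposed
into axial slices; slices whose mask has no foreground pixel are excluded
(they would contribute only trivially-empty references); remaining slices
are resized to the network input size — bilinear with anti-aliasing for
images, nearest-neighbour with re-binarization for masks. Predictions are
resized back nearest-neighbour and stacked at their original z indices,
with filtered positions filled with background, so the slice→volume round
trip is the identity on retained slices.

Fold assignment partitions slices into ten folds, stratified by quartile
of per-slice foreground area (the stratification variable is the package's
choice; it balances easy and hard slices across folds), dealt round-robin
so fold sizes differ by at most one. The three evaluation rounds are fixed:
E1 trains on {F1,F3,F4,F6,F7,F8,F10}, validates on {F2,F5}, tests on F9;
E2 on {F2,F4,F5,F6,F7,F9,F10}/{F1,F8}/F3; E3 on
{F1,F2,F3,F5,F7,F8,F9}/{F4,F6}/F10. Assignment is slice-level by default,
mirroring the slice-first-then-split procedure; this lets slices of one
patient straddle train and test, so a `group_by_volume` option deals whole
volumes to folds instead. Test metrics are computed on the round's
held-out fold only; validation losses are logged but never reported as
performance. Evaluation aggregates per-slice metrics by unweighted mean
(default), with a per-volume mean available.

## Synthetic phantoms

The phantom generator stands in for CT studies: each volume is a
soft-tissue background (0.3 on the normalized scale) containing one
brighter ellipsoidal organ (0.7) with additive Gaussian noise (σ = 0.05),
plus the exact voxelized ellipsoid as mask. Semi-axes and center are
sampled per volume (defaults: z semi-axis 4–7 voxels, in-plane 14–26 on a
24×96×96 grid; the tests use a 64×64 in-plane variant), and the organ's
z-extent is confined so that at least a configured fraction of slices
(default 25 %) is guaranteed mask-free, exercising the empty-slice filter.
Geometry is sampled before the noise field, so changing only the noise
level never changes the mask; the mask is a single 6-connected component
and its voxel count tracks the analytic ellipsoid volume 4πabc/3.

What the phantoms do *not* emulate: anatomical texture, neighbouring
organs of similar intensity, partial-volume boundaries, or CT
reconstruction artifacts. Passing the phantom suite therefore demonstrates
that the architecture, losses, pipeline and bookkeeping are correct and
that the network can learn an intensity/shape rule end-to-end — it says
nothing about segmentation accuracy on clinical CT.

## Compression

**Magnitude weight pruning** ranks the convolutional and
transposed-convolutional kernel weights globally by |w| ("throughout the
network"; a per-layer option exists) and zeroes the smallest
⌊fraction·P⌋, ties broken by flattened declaration order. Batch-norm
parameters and biases are out of scope — pruning them corrupts
normalization, and the kernel-only scope is what takes the reference
network from 1.0 M to 0.9 M nonzero at 15 %. A boolean mask is retained
per tensor so the nonzero accounting is exact and structural: a parameter
counts as removed only if masked, not if its float value happens to be 0.
No fine-tuning follows pruning.

**Filter pruning** removes, per channel-producing convolution (standard or
pointwise; the output head excluded), the ⌊fraction·F⌋ output filters with
smallest L1 kernel norm, then propagates the channel removals forward
through the graph: depthwise and depthwise-transposed layers drop the
matching channels, batch norms drop the matching affine/running entries,
and concatenations offset the surviving indices of each branch so that
consumers slice the correct input channels. The network's input/output
contract is preserved by construction and checked by a forward pass.

**Quantization** first folds each batch norm into its producing
convolution (W ← W·γ/√(σ²+ε) per output channel, bias ← β − μ·γ/√(σ²+ε)),
then stores every kernel as int8 with a symmetric per-tensor scale
max|w|/127, and calibrates asymmetric per-tensor activation ranges
(min–max over user-supplied calibration batches). Execution is emulated:
dequantized weights, activations fake-quantized to 256 levels — the
contract is storage (int8 payload ≈ 0.25× of float32 plus per-tensor
scale/zero-point) and numerics (each dequantized weight within half a
quantization step of its folded original), not an integer-kernel runtime.
Reported latency is informational and flagged hardware-dependent.

## Numerical and degenerate-case conventions

- Metrics on two empty masks return 1 (a prediction of nothing against an
  empty reference); the event is logged and rare because of the
  empty-slice filter. Predictions are binarized at probability 0.5.
- `round_millions_1dp` uses decimal round-half-up, so 950,000 → 1.0.
- Checkpoints are final-epoch weights (no early stopping); a
  best-validation selection can be layered on the per-epoch log.
- Forward passes in evaluation mode are deterministic; training is
  reproducible from the single run seed (fold shuffle, phantom sampling,
  weight init and batching all derive from it).

## Problem sizes used by the test suite

The end-to-end smoke run trains a width-reduced network (8/16/32/64,
bottleneck 128) on 64×64 phantom slices (16 volumes of depth 24, ~175
retained slices) for 10 epochs at batch size 8 — about a minute on one
CPU — and reaches training Dice ≥ 0.9 and held-out phantom-volume
IoU ≥ 0.8. The full-width reference network is built (for counting and
pruning accounting) but not trained in the tests; shape-contract forward
passes use 64–128 pixel inputs, which the divisible-by-16 contract covers.

## Known limitations

- 2D slice-wise inference ignores inter-slice context; ambiguous
  boundaries that neighbouring slices would disambiguate are a known
  failure mode of the approach.
- The NumPy engine targets correctness and desk-scale speed, not
  production throughput; full-resolution (512×512) training is out of its
  intended envelope.
- Quantized execution is emulated; real int8 deployment kernels may differ
  in rounding detail.
- Slice-level fold assignment can leak patient-level information between
  splits; use `group_by_volume=True` for patient-disjoint evaluation.
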