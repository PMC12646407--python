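# svncnet

Lightweight separable-convolution encoder–decoder network (SVNC-Net) for
slice-wise spleen segmentation from abdominal CT, together with its
slice↔volume data pipeline, training recipe, overlap metrics, and
post-training compression (weight/filter pruning and int8 quantization).

## Who this is for

Spleen volume estimated from CT underpins the diagnosis of splenomegaly,
and routine clinical deployment favours models that run in real time on
modest hardware. This package targets that regime: a U-shaped 2D network
small enough (~1 M parameters) for edge devices, applied slice by slice to
a 3D CT volume, with the per-slice predictions reassembled into a 3D mask.
Everything is testable at desk scale on synthetic ellipsoid phantoms — no
dataset download or GPU is required.

## The model

A four-stage encoder (channel widths 32–64–128–256) with 2×2 max-pooling,
a 512-channel bottleneck whose convolutions are dilated by 2, and a
mirrored decoder with concatenating skip connections. The first encoder
stage uses standard 3×3 convolutions; every later double-conv block is
depthwise-separable — a 3×3 per-channel (depthwise) filter followed by a
1×1 pointwise channel mix, each with batch normalization and ReLU. A
depthwise separable convolution costs

    D_k·D_k·M·D_f·D_f + M·N·D_f·D_f

multiply–accumulates against `D_k²·M·N·D_f²` for the standard operator, a
reduction of exactly `1/N + 1/D_k²`. Decoder upsampling is a depthwise 2×2
stride-2 transposed convolution followed by a 1×1 pointwise reduction; the
head is a 1×1 convolution with a sigmoid, giving per-pixel foreground
probabilities.

Training uses Adam with the compound loss
`L = α·L_Dice + (1−α)·L_BCE` (α = 0.5) and cosine annealing with warm
restarts (`η_max` 1e-3, `η_min` 1e-5, cycles of 10/20/20 epochs). Slices are
assigned to ten folds stratified by foreground area; three evaluation
rounds (E1–E3) each use 7 folds for training, 2 for validation and 1 for
testing. Reported metrics are IoU, two-class mean IoU (spleen + background)
and DSC, with DSC = 2·IoU/(1+IoU).

Post-training compression: 15 % global magnitude weight pruning over the
convolutional kernels (no fine-tuning), optional 20 % filter pruning with
full structural bookkeeping through the skip connections, and emulated
8-bit post-training quantization (symmetric per-tensor weights, min–max
calibrated activations, batch norm folded).

The network and its gradients are implemented on NumPy in a small static
graph engine (`svncnet.nn`); NIfTI I/O goes through nibabel and resampling
through scikit-image.

## Worked example

```python
import numpy as np
from svncnet import (ArchConfig, build_svnc_net, count_parameters,
                     PruneConfig, magnitude_weight_prune, compression_report,
                     dsc_from_iou, PhantomConfig, phantom_dataset,
                     RunConfig, ScheduleConfig, train_model, predict_volume,
                     MaskPair, iou)
from svncnet.phantom import generate_phantom
from svncnet.training import training_dice

model = build_svnc_net(ArchConfig(), seed=0)
s = count_parameters(model)
print(f"reference model: {s.total_params:,} trainable parameters "
      f"({s.params_millions_1dp:.1f} M)")

pruned = magnitude_weight_prune(model, PruneConfig(weight_fraction=0.15))
rep = compression_report(pruned, input_hw=(64, 64))
print(f"after 15% weight pruning: {rep.nonzero_params:,} nonzero "
      f"({rep.params_millions_1dp:.1f} M)")

print(f"DSC from IoU 0.89: {dsc_from_iou(0.89):.4f}")

arch = ArchConfig(input_size=64, stage_widths=(8, 16, 32, 64), bottleneck_width=128)
phantoms = PhantomConfig(shape=(24, 64, 64), n_volumes=16, seed=11,
                         semi_axes_range=((4.0, 7.0), (10.0, 18.0), (10.0, 18.0)),
                         center_jitter=5.0)
records, _ = phantom_dataset(phantoms, target_size=64)
run = RunConfig(arch=arch, schedule=ScheduleConfig(cycle_lengths=(10,)),
                epochs=10, batch_size=8, seed=7)
tiny = build_svnc_net(arch, seed=run.seed)
log = train_model(tiny, records, None, run)
print(f"trained {run.epochs} epochs on {len(records)} phantom slices; "
      f"final loss {log.final_train_loss:.3f}, "
      f"train Dice {training_dice(tiny, records):.3f}")

held_out = generate_phantom(PhantomConfig(shape=(24, 64, 64), n_volumes=1, seed=99,
                            semi_axes_range=((4.0, 7.0), (10.0, 18.0), (10.0, 18.0)),
                            center_jitter=5.0))[0]
pred = predict_volume(tiny, held_out, target_size=64)
print(f"held-out phantom volume IoU: {iou(MaskPair(pred, held_out.mask)):.3f}")
```

Output:

```
reference model: 1,034,785 trainable parameters (1.0 M)
after 15% weight pruning: 881,718 nonzero (0.9 M)
DSC from IoU 0.89: 0.9418
trained 10 epochs on 177 phantom slices; final loss 0.350, train Dice 0.942
held-out phantom volume IoU: 0.910
```

The reference network rounds to 1.0 M trainable parameters; global 15 %
magnitude pruning of the kernels leaves 0.9 M nonzero — a 10 % cut in the
one-decimal figure. A width-reduced variant trained for ten epochs on
synthetic phantoms segments a held-out phantom volume at IoU 0.91.

## Command line

```
svncnet --config run.yaml --seed 5 --out out phantom     # synthetic NIfTI volumes
svncnet --config run.yaml --seed 5 --out out prepare     # slice/filter/resize + manifest
svncnet --config run.yaml --seed 5 --out out train --round E1
svncnet --out out predict out/checkpoint.npz volume.nii.gz
svncnet --config run.yaml --seed 5 --out out evaluate out/checkpoint.npz --round E1
svncnet --config run.yaml --out out compress out/checkpoint.npz
```

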