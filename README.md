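# edtnet

Transformer encoder–decoder segmentation of pulmonary nodules in 2-D
CT-like images, with a fully synthetic phantom pipeline so the whole
system — data, training, evaluation, ablations — runs end to end on one
CPU with no clinical data.

## Who this is for

Researchers who want an executable, tested reference of a *spatially
biased* windowed-attention U-Net for binary medical-image segmentation:
every architectural component is an inspectable module with oracle-backed
tests, and a phantom generator stands in for CT data so experiments are
reproducible from a seed.

## The model

EDTNet is a U-shaped encoder–decoder built from transformer blocks whose
attention carries a learnable relative spatial bias. For tokens on an
`h × w` grid, each head computes

```
A = softmax(Q Kᵀ / √d_head + S) V,     S_ij = W_s[P_i − P_j]
```

with `W_s` a per-head lookup table over relative offsets — translation
invariant, one table per attention scope. Local blocks (**ESLA**) run
this attention inside non-overlapping 8×8 windows in the encoder and
decoder stages; global blocks (**ESGA**) use a single full-grid scope in
the bottleneck. Skip connections are *skip attention*: decoder tokens
query the same-resolution encoder tokens by cross attention and add the
result residually. A convolutional patch embedding (with learnable
positional encodings) enters the network; stride-2 convolutions
downsample; stride-2 transposed convolutions upsample; a patch-expanding
head returns full-resolution logits. Training minimizes the hybrid loss

```
L = α · DiceLoss(Y, Y′) + (1 − α) · CrossEntropy(Y, Y′),   α = 0.5
```

and evaluation reports precision, sensitivity, IoU and DSC from pixel
confusion counts. `docs/methods.md` documents every design choice and
the phantom generator in detail.

The network, autodiff engine (`edtnet.autodiff` — reverse-mode on NumPy
arrays, float64, finite-difference-validated) and training stack are all
in this package; NumPy/Pillow/pandas handle arrays and I/O.

## Worked example

Deliberately overfit the tiny network (64-px phantoms, ~260k parameters)
on eight generated phantoms and check how it transfers to eight fresh
ones from the same generator:

```python
from edtnet.pipeline import overfit_benchmark

res = overfit_benchmark(train_seed=42, holdout_seed=43, model_seed=0, steps=200)
print({k: round(v, 4) for k, v in res["train"].items()})
print({k: round(v, 4) for k, v in res["holdout"].items()})
print("loss %.4f -> %.4f" % (res["loss_history"][0], res["loss_history"][-1]))
```

prints

```
{'precision': 0.9768, 'sensitivity': 0.9842, 'iou': 0.9616, 'dsc': 0.9803}
{'precision': 0.8327, 'sensitivity': 0.8203, 'iou': 0.6729, 'dsc': 0.7965}
loss 0.8989 -> 0.0219
```

Reading: after 200 Adam steps the model reproduces the eight training
masks almost perfectly (train IoU 0.96 — the memorization sanity check
passes), while held-out phantoms score IoU ≈ 0.67 — genuine but limited
generalization, which is the expected behaviour of an attention-only
model trained from scratch on eight source images. The held-out figure
varies by a few points across generator seeds.

The same machinery is scriptable from the shell:

```
edtnet generate --n 204 --size 256 --seed 0 --augment --out data/   # 1224 samples
edtnet train   --data data/ --out run/ --epochs 200
edtnet eval    --ckpt run/checkpoint.npz --data data/
edtnet predict --ckpt run/checkpoint.npz --image slice.png --threshold 0.5
edtnet ablate  --data data/ --out ablation/ --variants all
```

`generate` writes PNG image/mask pairs plus a CSV manifest; `train` logs
`epoch,train_loss,val_loss,val_iou` to CSV, saves a checkpoint with the
config embedded, and plots the loss curve; `ablate` trains the five
component variants (patch merging vs convolutional downsampling, linear
vs convolutional embedding, local/global depths, skip attention) under
one seed and tabulates `label,params,mean_iou,mean_dsc`.

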