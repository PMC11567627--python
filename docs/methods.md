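# Methods

## The model

EDTNet is a U-shaped encoder–decoder for binary segmentation of pulmonary
nodules in 2-D CT slices, built entirely from transformer blocks whose
attention scores carry a learnable *relative spatial bias*. For tokens
`i, j` on an `h × w` grid with positions `P_i, P_j`, each head computes

    A = softmax(Q Kᵀ / √d_head + S) V,      S_ij = W_s[P_i − P_j]

where `W_s` is a per-head table indexed by the relative offset
`(Δrow, Δcol)` — `(2m_h − 1)(2m_w − 1)` entries for an `m_h × m_w`
attention scope. The bias is translation invariant by construction and its
parameter count is independent of image size per scope. Two scopes are
used:

* **ESLA** (spatially aware local attention): the token grid is tiled into
  non-overlapping square windows (default side 8) and biased attention
  runs inside each window. The window tiling is our realization of
  "local"; no shifted-window scheme is used.
* **ESGA** (spatially aware global attention): one scope spanning the
  whole bottleneck grid. ESLA with a full-grid window is numerically
  identical to ESGA, which the test suite asserts to 1e-6.

Block anatomy is standard pre-norm ViT practice: layer norm → windowed
biased multi-head attention → residual → layer norm → 2-layer MLP
(expansion 4, GELU) → residual.

The network layout, for a 256-px image with embed stride 4 and base width
C:

| stage | grid | width |
|---|---|---|
| convolutional patch embed + learnable PE | 64×64 | C |
| encoder stage 1: `esla_depth` × ESLA | 64×64 | C |
| downsample (stride-2 conv or patch merging) | 32×32 | 2C |
| encoder stage 2: `esla_depth` × ESLA | 32×32 | 2C |
| bottleneck downsample | 16×16 | 4C |
| `esga_depth` × ESGA | 16×16 | 4C |
| bottleneck upsample (stride-2 deconv) | 32×32 | 2C |
| +PE_dec, skip attention ← encoder stage 2, `esla_depth` × ESLA | 32×32 | 2C |
| upsample (stride-2 deconv) | 64×64 | C |
| +PE_dec, skip attention ← encoder stage 1, `esla_depth` × ESLA | 64×64 | C |
| patch-expand head | 256×256 | 1 |

Skip attention replaces concatenation skips: decoder tokens query the
same-resolution encoder tokens through cross attention (decoder queries
via a distinct projection W′, never shared with W_Q; keys and values from
the encoder stream) and the result is added residually, so a zero value
projection passes the decoder through unchanged. Decoder positional
encodings are added to the decoder stream before the skip attention.

The head expands tokens back to pixel resolution with a
stride-`embed_stride` transposed convolution at a small channel width
(8), followed by GELU and a 5×5 refinement convolution producing one
logit channel. The 5×5 receptive field is on the order of a small nodule
diameter; in development it recovered visibly sharper boundaries than a
bare deconvolution on both fitted and held-out phantoms. Probabilities
are `sigmoid(logits)`, binarized at 0.5.

Design choices the architecture family leaves genuinely open, fixed here:
`D_k` is read as √d_head (standard scaled dot-product);
the function combining positions and learnable weights in the spatial
bias is realized as the offset lookup above; the bottleneck order is
downsample → global blocks → upsample; the decoder stage order is
upsample → PE → skip attention → local blocks. The global-block depth is a config field (`esga_depth`, default 3; the
strongest ablation variant uses 2), so both depths are expressible.

## Loss and metrics

Training minimizes the hybrid loss
`L = α·DiceLoss + (1 − α)·BCE` with α = 0.5 by default (the neutral
choice; configurable). Soft Dice uses smoothing ε = 1e-6; BCE clips
probabilities at 1e-7. On hard masks with ε = 0 the Dice loss equals
1 − DSC exactly.

Evaluation uses pixel confusion counts: precision TP/(TP+FP), sensitivity
TP/(TP+FN), IoU TP/(TP+FP+FN), DSC 2TP/(2TP+FP+FN). Sensitivity and Dice appear in the literature in several
typographical variants, some internally inconsistent; the standard,
self-consistent forms above are used. When a denominator is zero the
metric is 1 if TP = FP = FN = 0 (vacuously perfect) and 0 otherwise.

## The phantom generator

No clinical data ships with the package; the generator emulates the
appearance statistics that matter for this segmentation task:

* mid-grey soft-tissue background (intensity 0.55);
* two dark elliptical lung fields (axes 0.32/0.20 of the image side,
  interior intensity 0.18);
* 2–6 bright curvilinear vessel distractors (+0.22) confined to the lung
  interiors — these create nodule-like local contrast that a segmenter
  must reject;
* 1–3 bright circular nodules (radius 3–12 px at 256 px, contrast
  +0.25–0.5) centred inside a lung field; the mask is exactly the union
  of the nodule disks;
* additive Gaussian noise (σ = 0.02), then clamping to [0, 1], and
  replication to three identical channels.

`PhantomSpec.roi(64)` is the desk-scale regime used throughout the test
suite: 64-px fields with nodule radius 3–8 px and 1–2 nodules, emulating
the common protocol of cropping a small patch around each nodule centroid
(where the nodule occupies a larger fraction of the field than in a full
axial slice). A naive 4× downscale of the 256-px defaults would make nodules
sub-pixel, which no scanner-realistic phantom should do.

What the phantoms do **not** model: HU calibration, 3-D partial-volume
effects, non-circular or juxtapleural nodules, texture inside lesions,
and scanner reconstruction artifacts. Passing tests therefore demonstrate
that the architecture, losses, training loop and bookkeeping behave as
specified — not clinical-grade segmentation performance.

## Augmentation, splitting, persistence

Each sample expands sixfold: original, horizontal flip, vertical flip,
90° and 180° rotations, and a central 75% crop resized back (bilinear
image, nearest-neighbour mask). 204 sources therefore yield 1224 samples.
The 80/20 split has two modes: *leak-free* (default) partitions over
source ids so augmented copies of one original never straddle the split —
the floor arithmetic then applies to the group count; the non-leak-free
mode partitions the augmented pool directly and satisfies
`|train| = floor(0.8·n)` exactly (1224 → 979/245). The classical protocol augments before splitting (the non-leak-free
mode); the leak-free mode is sounder validation practice, so both are
provided with leak-free as default. Datasets
persist as 8-bit PNGs plus a CSV manifest; masks round-trip bit-exactly,
images within 1/255.

## Training

Adam (β = 0.9/0.999, ε = 1e-8); learning-rate schedule, weight decay,
gradient clipping and early stopping are all off by default and
configurable. The full-scale profile is batch 64, 200 epochs, learning
rate 1e-4 on 256-px images with C = 96, heads (3, 6, 12), head dim 32;
that profile is preserved but never trained at desk scale. The tiny
preset (64-px images, C = 16, head dim 8, ~270k parameters) trains with
batch 8–32 and learning rate 1e-3–5e-3, the standard Adam range for a
model this small. All randomness — init, split, shuffling — derives from
explicit seeds; two identical runs produce bit-identical checkpoints.

Inference offers optional test-time averaging over exactly the flip and
right-angle-rotation transforms the augmentation set trains invariance
to; averaging over a larger symmetry group (e.g. transposes) was measured
to *hurt*, since the model is only invariant to transforms it saw.

## The deliberate-overfit benchmark

`overfit_benchmark()` pins the package's end-to-end sanity check: 8 ROI
phantoms (seed 42), expanded sixfold, 200 Adam steps at batch 32,
learning rate 5e-3 with a 20-step linear warmup, then TTA evaluation on
the training phantoms and on 8 freshly generated held-out phantoms
(seed 43). Typical results: training IoU ≈ 0.96, held-out IoU ≈ 0.6–0.7.
The held-out figure varies by roughly ±0.05 across generator draws and
parameter inits — with eight training sources the variance of
generalization is irreducibly large, and we report it as measured rather
than tuning conditions around it.

## Numerical choices

Everything runs in float64 on a NumPy reverse-mode autodiff engine
written for this package (`edtnet.autodiff`): broadcasting arithmetic,
batched matmul, softmax, sigmoid, fused GELU (tanh approximation) and
layer norm, strided convolution, transposed convolution, and the
offset-table gather. Every primitive is validated against central finite
differences at 1e-6; softmax rows are asserted to sum to 1 within 1e-5
everywhere attention is computed. The backward pass frees the tape
eagerly, keeping training memory flat. Degenerate inputs fail loudly:
non-finite tokens, shape mismatches, odd grids for 2× resampling,
non-binary masks and empty datasets all raise with the offending
quantity named.

## Ablation harness

The five-variant component matrix is executable: (1) 1×ESLA + patch
merging + linear patch embedding with PE; (2) as (1) with convolutional
embedding; (3) as (2) with convolutional downsampling; (4) as (3) plus
one ESGA block; (5) the full model — 2×ESLA, 2×ESGA, convolutional
downsampling and embedding, skip attention. All five train under an
identical RunConfig and seed and tabulate parameter count, validation
mean IoU and DSC. Row 1's "PE" label is interpreted as linear patch
embedding + learnable positional encoding (the row-2 delta is then
exactly the embedding swap); positional encodings themselves are present
in every variant.

## Known limitations

2-D binary segmentation only; no DICOM/NIfTI ingestion (PNG + CSV
manifests); no shifted windows, sparse attention, mixed precision or
multi-device training; CPU-bound float64 throughput limits practical
training to the tiny profile; quantitative claims about clinical data are
out of scope by design.
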