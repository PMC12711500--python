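# Methods

## The model

CASPNet is a hybrid image classifier for cropped single-cell Pap-smear
images (the five-class SIPAKMED setting: Dyskeratotic, Koilocytotic,
Metaplastic, Parabasal, Superficial-Intermediate). It composes three
ideas: a ViT-Base token encoder for global context, a YOLO-style
cross-stage-partial (CSP) block for local feature fusion, and a
spatial-pyramid-pooling-fast (SPPF) block for multi-scale aggregation.
The bridge between the two worlds is deliberately parameter-free:

```
image (B,3,224,224)
  └─ patch conv, 16×16 stride 16, →768 dims     → (B,196,768)
  └─ + CLS token, + learned positions, dropout  → (B,197,768)
  └─ 12 pre-norm transformer blocks, final LN   → (B,197,768)
  └─ drop CLS, reshape row-major onto 14×14     → (B,768,14,14)
  └─ CSP block                                  → (B,768,14,14)
  └─ SPPF block                                 → (B,768,14,14)
  └─ global average pool                        → (B,768)
  └─ LN → 512 → 256 → 5 MLP head                → (B,5) logits
```

Each transformer block is the standard pre-norm residual pair
`x += MHSA(LN(x)); x += MLP(LN(x))` with 12 heads of dimension 64
(attention scale 1/√64 = 0.125), an MLP expansion of 4×, QKV bias, and
dropout 0.1 on attention weights, projections and MLP.

The token-to-spatial reshape discards the class token and places patch
token *k* (0-based) at grid cell (k // 14, k % 14), channels first. It
is exactly invertible and contributes zero parameters; the row-major
convention is fixed so round-trip tests are well defined.

**CSP block.** Two parallel 1×1 conv units reduce 768 → 384 channels.
Branch 1 is the shortcut; branch 2 is flattened to 196 tokens of
dimension 384 and refined by one transformer block with 6 heads
(keeping head dimension 64), then reshaped back. The branches are
concatenated (384 + 384 = 768) and merged by a 1×1 conv unit 768 → 768.
The merge conv is required to restore the channel width; the published
block table omits it.

**SPPF block.** A 1×1 reduction 768 → 384, then three cascaded 5×5
stride-1 max-pools (padding 2). Cascaded 5×5 pools have effective
receptive fields of 9×9 and 13×13 — an equivalence the tests verify
against a brute-force sliding-window maximum. The four maps (1536
channels) are merged by a 1×1 conv back to 768.

**Conv units** are convolution → SiLU with no normalization layer. A
batch-norm variant was considered and not implemented: it adds
train/eval statistics machinery for no tested behaviour, and the
parameter budget already matches the published figure without it.

**Classification head.** LayerNorm(768) → 768→512 → GELU → dropout →
512→256 → GELU → dropout → 256→5, returning raw logits. The published
description says only "hierarchical fully-connected network"; these
widths close the total budget to the published 90.76 M parameters.

### Parameter budget

| component | parameters |
|---|---:|
| patch conv | 590,592 |
| CLS + positional embeddings | 152,064 |
| 12 transformer blocks | 85,054,464 |
| final encoder LayerNorm | 1,536 |
| CSP block | 2,955,648 |
| SPPF block | 1,475,712 |
| head | 527,877 |
| **total** | **90,757,893 (90.76 M)** |

The patch-embedding normalization is a LayerNorm *without* learned
affine parameters: normalization is applied as described, and the
backbone count stays at the hand-derived 85,798,656 (with a learned
affine both readings still round to 90.76 M, so this is a bookkeeping
choice, not a capacity one).

### Ablation variants

All variants share one `ArchConfig`. `full` is the pipeline above;
`vit_only` classifies from the CLS token (no CSP/SPPF); `vit_csp` drops
only the SPPF block; `csp_sppf_only` reuses the patch conv as a
16-stride stem straight into the spatial grid (no class token, no
encoder). The published ablation table's parameter figures for the
partial variants are internally inconsistent (its ViT row lists 0.046 M
against an ~85.8 M backbone); this package reports the true counts and
asserts only the relationships that are arithmetically checkable, e.g.
count(full) − count(vit_csp) = 1,475,712 exactly.

### FLOP accounting

FLOPs are counted as one multiply-accumulate per matrix-product scalar,
over convolutions, linear layers and the attention products QKᵀ and
attention×V; normalizations, activations, pooling and element-wise ops
are excluded. Counting is done by instrumenting the matmul primitive
during a real batch-1 forward pass, so it is exact for any geometry.
Under this convention the full model measures 18.460 G MACs at 224 px —
within 5 % of the published 17.731 G, whose counting convention is not
stated; the figure is reported, never asserted.

## Numerical core

No deep-learning framework is used: the package carries a small
tape-based reverse-mode autodiff engine over float32 NumPy arrays
(broadcasted arithmetic, batched matmul, reductions, reshapes, softmax
and log-softmax with max subtraction, layer normalization, GELU via the
exact error function, SiLU, sliding-window max pooling with argmax
routing in the backward pass, inverted dropout). Parameters are
float32; oracle comparisons therefore bottom out near 1e-6 absolute,
and the test tolerances reflect that floor. Initialization is
truncated-normal (σ = 0.02, clipped at 2σ) for weights and embeddings
and zeros for biases; a single global generator seeds initialization
and dropout, so whole runs are reproducible from one integer.

## Training recipe

Loss is multi-class cross-entropy (mean over the batch, computed by
stable log-softmax). The optimizer is AdamW with the decoupled update

  θ ← θ − η·m̂/(√v̂ + ε) − η·λ·θ,

λ = 0.05, and standard defaults β₁ = 0.9, β₂ = 0.999, ε = 1e-8 (the
source declares the symbols but not the values). Decay applies to
weight matrices only — biases, norm parameters and the CLS/positional
embeddings are excluded, following common transformer practice. The
additive L2 form λ·Σw² is available as a reporting quantity only; it is
never added to the gradient, avoiding double decay.

The learning rate follows a one-cycle cosine schedule stepped per
optimizer step: cosine warm-up 1e-4 → 1e-3 over the first 10 % of total
steps, then cosine annealing 1e-3 → 1e-5, continuous at the peak.
Batch size 128, 450 epochs and seed 1337 are the configured defaults of
the published recipe; desk-scale runs override them.

Data handling: one sub-directory per class, alphabetical class indices.
The 80:10:10 stratified holdout is made deterministic by a fixed rule —
per class, shuffle with a generator seeded by (seed, class index),
assign round(0.1·n) items to test, the next round(0.1·n) to val
(round half-up), remainder to train. On the published class sizes this
rule yields 403 test items; the source reports 409, and its exact
assignment rule is not recoverable, so the deterministic rule above is
the contract. Training-time augmentation (random-resized crop to 224,
horizontal/vertical flips at p = 0.5, ±20° rotation, color jitter 0.1
on brightness/contrast/saturation/hue) is applied on the fly to the
training split only; the crop scale range (0.6, 1.0) and
median-border-color rotation fill are this package's choices where the
recipe is silent. Evaluation uses a deterministic resize and
standardization with the common natural-image statistics (overridable).

## Synthetic fixtures

The fixture generator renders class-conditional single-cell cartoons:
background noise, a cytoplasm ellipse, a nucleus ellipse and chromatin
speckles, with per-class ranges for the nucleus-to-cytoplasm (N:C) area
ratio, nucleus eccentricity, speckle density and stain darkness — the
same morphological axes a cytologist reads (high N:C and hyperchromasia
for dysplastic cells). A five-class profile mirrors the published
per-class image counts; a two-class "tiny" profile differs *only* in
nucleus size, so any classifier separating it must attend to the
nucleus, giving the attribution tests a falsifiable target. Every image
derives its RNG stream from (seed, class, index), so regeneration is
byte-identical. Ground-truth nucleus masks are emitted alongside.

What passing on fixtures shows — and does not. The synthetic classes
are separable by construction and carry no staining variability,
overlapping cells, debris or focus artifacts; success here validates
the pipeline's mechanics (shapes, gradients, optimization, attribution
plumbing), not clinical performance. Reproducing the published 97.07 %
test accuracy requires the real benchmark and a long GPU run, and is
out of scope by design.

## Explainability

Grad-CAM hooks the SPPF output (the final convolutional map, 768×14×14
at default geometry; the CSP merge output is available behind a flag).
Channel weights are spatial means of the target-logit gradients; the
raw map is the ReLU of the weighted channel sum, min-max normalized per
image (an all-zero map stays zero) and bilinearly upsampled to input
resolution. The computation reads gradients only and never mutates
parameters. Localization is scored as the fraction of heatmap mass
inside the (optionally dilated) nucleus mask, compared against the
mask-area-fraction baseline a uniform heatmap would score.

## Problem sizes in the test suite

The suite exercises the full-size model only where the claim demands it
(parameter accounting, the 224 px shape contract, the FLOP report); all
learning runs use a depth-reduced configuration (64 px input, embed 64,
depth 2, 4 heads, widths 32) on 64 synthetic images, which a CPU
overfits to ≥95 % training accuracy within 200 optimizer steps. Oracle
checks run on toy geometries where brute force is exact.

## Known limitations

- float32 throughout; no mixed precision, no GPU path, single process.
- Positional embeddings are fixed to the configured grid; there is no
  interpolation for other input sizes (the conv-stem variant accepts
  any divisible geometry).
- The augmentation pipeline works on PIL images and is not vectorized;
  it is sized for desk-scale runs.
- Checkpoints embed the architecture config and round-trip bitwise, but
  no cross-version migration is attempted.
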