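# Methods

## The model

`dranet` implements a binary segmentation network for stained-tissue
images built from three parts:

1. **Convolutional encoder-decoder.** A five-stage ResNet-style encoder
   (7×7 stride-2 stem, 3×3 stride-2 max-pool, then residual basic blocks with
   two 3×3 convolutions each; two blocks per non-stem stage) produces
   features at 1/2 … 1/32 of the input resolution. Group normalization
   (8 channels-per-group by default) replaces batch normalization so that
   statistics are independent of the small batch size (4) used in training.
   The decoder mirrors the encoder: each stage upsamples bilinearly
   (half-pixel centers, edges clamped), concatenates the same-level encoder
   feature through a long skip connection, and refines with two
   conv–norm–ReLU pairs; a 1×1 convolution and sigmoid produce the
   full-resolution foreground probability map.

2. **Ordered shift MLP block.** Channels are ranked by a learned importance
   score — a shared two-layer bottleneck MLP (reduction 4) applied to the
   spatially average-pooled and max-pooled channel vectors, summed — and
   gathered into descending-score order (ties keep ascending original
   index, so the ordering is deterministic). The ordered channels are split
   into `g` contiguous groups and each group is displaced a few pixels
   along one spatial axis with zero fill, so subsequent per-position MLPs
   mix neighbouring locations. The block runs this twice — height first,
   then width — with a positional token MLP (channel MLP → depthwise
   separable 3×3 convolution → GELU) between, a re-ranking from the
   intermediate feature, and a final channel MLP.

3. **Dynamic regional attention (DRA).** The stage feature is collapsed to
   one channel by a per-pixel projection, partitioned into `k`
   non-overlapping regions of mutually similar pixels, fused by replacing
   each pixel with its region mean, and squashed through a sigmoid to form
   an H×W gate. Similarity between a pixel and a region center combines
   feature proximity `d_f = |x_i − x_j|` and spatial proximity `d_s`
   (Euclidean pixel distance) as `S = sqrt((d_f/m)² + (d_s/s)²)` with
   `s = sqrt(H·W/k)`. Two search modes exist: **local** (the default) is a
   SLIC-style superpixel clustering — centers start on a regular
   ⌈√k⌉-spaced grid and each pixel is assigned among centers within a 2s
   window; **global** drops the spatial term and searches all centers,
   which makes it exactly one-dimensional k-means on pixel values with
   grid-sampled initial centers. Both run a fixed number of
   assignment/update rounds (5 by default).

At each configured encoder stage (the deepest only, by default) the
convolutional stream `Y` is augmented residually:
`Y ← Y + gate(Y) ⊗ osmlp(Y)` for the full model, with the obvious
reductions for the ablation variants (`Y + osmlp(Y)`, `Y + gate(Y) ⊗ Y`).
Gating the MLP branch rather than a separate branch keeps the DRA
parameter cost to the projection alone, consistent with the published
parameter budget.

## Loss and metrics

Training minimizes `0.5·BCE + Dice` on the probability map. BCE clips
predictions to `(1e-7, 1−1e-7)`; the soft Dice term uses smoothing 1.0 in
the training loss (stable gradients on empty masks) and ~0 in metric
cross-checks (numeric fidelity). Evaluation binarizes at 0.5 and reports
IoU, Dice, recall, specificity and precision as percentages from per-image
confusion counts; per-image averaging is the default aggregate, with a
pooled-pixel mode available (published tables do not state which is used,
so both exist). Degenerate denominators (a class absent from both maps)
score 100%.

## Differentiability contract

The network trains on a small reverse-mode automatic differentiation core
over numpy (`dranet.nn`), written for this package; each primitive's
backward rule is validated against central finite differences in the test
suite (agreement to 1e-4 relative tolerance through the full blocks). Two
computations are deliberately outside differentiation: the channel ordering
(an argsort) and the region assignment (a discrete labeling). Gradients
flow through the token/channel MLPs, the DRA projection and the region
means; the score MLPs that produce the ordering receive no gradient and act
as fixed random projections after initialization — a property of the
published design, since sorting is not differentiable. Their parameters are
still counted in the budgets.

## Parameter budget

The architecture's free widths were set so that the default 224×224 model
reproduces the published ablation budgets to two decimals: 14.32 M
(convolutional stream only), 15.27 M (+MLP block, Δ≈0.95 M), 14.33 M
(+DRA, Δ≈0.01 M), 15.28 M (both). Concretely: decoder widths
(240, 144, 88, 40); ordered-shift MLP hidden width 204 and score bottleneck
128 at 512 channels; DRA projection hidden width 14 (the `C→h→1` per-pixel
MLP carries the ~0.01 M DRA delta; the single-layer `C→1` projection of the
basic operation remains available). Hidden widths scale proportionally with
the channel count for narrower configurations. FLOPs are reported as
multiply–accumulates (1 MAC = 1 FLOP) with the DRA distance search counted
explicitly: `16·H·W` distances per round in local mode (k centers × (4s)²
window), `H·W·k` in global mode.

## Training defaults

Adam (weight decay 1e-4), initial learning rate 1e-3 cosine-annealed to
1e-5 over the run, batch size 4, 400 epochs at 224×224 — the published
recipe — with right-angle rotations, horizontal/vertical flips (p = 0.5) and
±20% contrast jitter (the augmentation magnitudes are this package's
defaults; only the augmentation kinds are published). One master seed
drives the train/val split (10% held out for checkpoint selection),
shuffling, augmentation and weight initialization, and is stored in the
checkpoint, so evaluation and metric paths are bit-reproducible.

## Synthetic data

The generator renders elliptical or ring-shaped (lumen-bearing) objects in
an eosin-pink / hematoxylin-purple palette with multiplicative value-noise
texture, Gaussian-blurred boundaries and additive noise; the binary mask is
rasterized before blurring, so it is exact. Object bounding circles are
kept at least 3 px apart, so connected components equal the object count.
Presets: `easy` (compact solid blobs, mild noise), `hard` (rings, heavy
blur/noise), and `glas_like` / `cocahis_like` mirroring the qualitative
contrast between compact glandular rings and scattered irregular blobs in
the two public benchmarks. What these images do **not** emulate: nuclei-
level texture, stain variability across slides, touching glands, and
annotation noise — so passing tests demonstrate that the pipeline learns
and evaluates correctly, not that it reaches benchmark-level accuracy on
real histology.

## CPU-scale study conditions

The demonstration runs (tests and `scripts/acceptance.py`) train a
reduced-width full model — stage widths (16, 16, 32, 64, 128), decoder
(32, 24, 16, 16) — for 30 epochs on 64 easy-preset 96×96 images, reaching
held-out Dice ≥ 0.85 within minutes on one CPU core. The k-sweep protocol
(k ∈ {5, 10, 15, 20, 25}, all other configuration shared) and both search
modes run end-to-end at further reduced sizes, with the DRA block placed at
the 1/8-resolution stage so an 8×8 map admits k = 25. These sizes are the
package's own CPU-scale profile; full-scale training (400 epochs, 224×224,
the public datasets) uses the same code paths via the CLI.

## Numerical choices

- Channel-order ties: stable argsort on negated scores (descending score,
  ascending index).
- Shift offsets: symmetric window `i − ⌊g/2⌋` for group `i`; default group
  count 4 at the 512-channel site (the channel count must divide evenly;
  with an even count the window is near-symmetric).
- DRA feature values are standardized to unit variance before distance
  computation; `m = 10` on that scale. Recorded region centers are
  converted back to raw units.
- Empty regions after a center update are repaired by reseeding at the
  pixel farthest (by S) from its current center, so the partition always
  uses exactly k labels.
- Bilinear resampling uses half-pixel centers without corner alignment,
  matching the mask resizing convention (nearest neighbor, half-pixel).
- The second channel ranking is computed from the intermediate feature (the
  branch input at that point); a config switch
  (`second_order_from_input=True`) preserves the literal re-use of the
  block input. The per-pixel channel collapse reading of the DRA projection
  follows the prose description; a flatten-everything reading is
  dimensionally inconsistent and is not implemented.

## Known limitations

- Pure-numpy training is practical only at reduced widths/resolutions;
  full-scale 224×224 runs are possible but slow on CPU.
- No pretrained-weight import, multi-class heads or 3-D volumes.
- No connectivity enforcement or region merging in the partition;
  assignments are hard (no probabilistic variant).
- Learned offsets or multi-scale shift variants are out of scope.
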