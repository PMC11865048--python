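# Methods

`mungseed` implements a complete image-classification pipeline for mung-bean
(*Vigna radiata*) seed varieties photographed on a dark absorbent cloth:
threshold segmentation into per-seed crops, offline data enhancement, a
lightweight attention CNN ("HP" variant of MobileNetV2), a calibrated cost
profiler, an SGD training harness, evaluation metrics and Grad-CAM. Because
the original photographs are not redistributable, the package ships a
synthetic scene generator that reproduces the *geometry and statistics* of
the acquisition setup, and every stage is specified and tested against it.

## Synthetic seed photographs

A scene is a near-black background (gray level 0.05, Gaussian sensor noise
sd 0.01, clipped to ≤ 0.2) with bright ellipsoidal seed blobs placed on an
(rows × cols) grid — the physical tray holds 200 seeds in a 10 × 20
arrangement, and single-seed 224 × 224 crops are the degenerate 1 × 1 grid.
Each variety is a distribution over hue (means evenly spaced on the colour
wheel, sd 0.02), ellipse semi-axes (≈ 60 × 46 px at 224-px scale, sd 4),
HSV value (class means 0.68–0.80, per-seed sd 0.02, clipped to ≥ 0.55) and
additive texture noise (amplitude 0.02). Saturation stays ≤ 0.18 so that the
BT.601 luma of any seed pixel, for any hue, stays well above the 0.4
segmentation threshold; thresholding a generated scene recovers the
ground-truth mask with ≥ 99 % pixel agreement (the residual disagreement is
the one-pixel anti-aliased rim). Ellipses are confined to their grid cell
(axes capped, centre jitter bounded), so bounding boxes are disjoint by
construction — the acquisition protocol excludes touching seeds, and so does
the generator.

All randomness flows from one integer seed; image *i* of a dataset uses
sub-seed `(seed · 1000003 + i) mod 2^31`.

What the generator does **not** emulate: real seed-coat texture, specular
highlights, shadows, lens distortion, or the subtle inter-variety
differences that make the real task hard. Synthetic classes are separated
mainly by hue, so a passing training run demonstrates that the pipeline
*learns and is wired correctly*, not that the architecture reaches any
particular accuracy on real seeds.

## Segmentation

Grayscale uses ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B) on
[0, 1]-scaled channels. Binarisation at threshold 0.4 maps a pixel exactly
equal to the threshold to 1 (the published rule fixes only the strict
cases). The mask multiplies the RGB image pixel-wise; target regions are
8-connected components, filtered by a minimum area (default 50 px, rejecting
speckle), padded by 4 px, and resized bilinearly to 224 × 224. Component
labelling is equivalent to contour following for disjoint blobs and is the
better-conditioned primitive. Manual removal of blurred/damaged captures is
replaced by the area filter plus an optional Laplacian-variance blur filter,
off by default.

## Data enhancement and split

Each effective image yields itself plus four variants (5× exactly):
brightness × 2 (PIL `ImageEnhance.Brightness`), additive Gaussian noise with
mean 1 and sd 1.5 *on the 0–255 intensity scale* (a deliberately tiny
perturbation; clipped to [0, 255]), a horizontal mirror, and a 90°
counter-clockwise rotation (exact index permutation on square crops). Mirror
axis and angle are configurable; the defaults are the package's choice.

The 8:1:1 split is stratified per class with integer arithmetic
`train = ⌊0.8 N⌋, val = ⌊0.1 N⌋, test = N − train − val`; this rule
reproduces every published per-variety train/val/test cell (e.g. 4405 →
3524/440/441) and the totals 27,912 / 3,487 / 3,491 from 34,890. Splitting
happens after enhancement, so variants of one source image may cross splits;
`group_by_source=True` prevents that for leak-free evaluation.

## Architecture

The baseline is stock MobileNetV2: stem 3×3/2 conv to 32 channels, 17
inverted-residual bottlenecks in seven stages (t, c, n, s) =
(1,16,1,1), (6,24,2,2), (6,32,3,2), (6,64,4,2), (6,96,3,1), (6,160,3,2),
(6,320,1,1), a 1×1 head conv to 1280, global average pooling and a 1×1
convolution to k logits. A bottleneck expands channels by t with a 1×1 conv,
filters with a 3×3 depthwise conv (stride s on the first repeat), and
projects linearly with a 1×1 conv; the shortcut exists only at stride 1 with
matching channels. With k = 8 this counts 2,234,120 trainable scalars
(2.234 M).

The HP variant modifies every bottleneck and keeps the topology:

- **Mish** (`x·tanh(softplus x)`) replaces ReLU6 at both activation sites
  and after the stem/head convs. Smooth, non-monotonic, global minimum
  ≈ −0.3088.
- **DMS block** on the expanded width, inserted after the depthwise stage:
  adaptive average pool to 5 × 5 (capped at the input size when smaller) →
  depthwise 3×3 with bias → Mish → depthwise 3×3 without bias → Sigmoid →
  nearest-neighbour upsample to the block's spatial size → `out = x + x ⊙
  gate`. 19 parameters per channel; summed over the 17 bottlenecks the
  expanded widths total 7,136 channels. The internal wiring of this block is
  under-determined by its prose description; this resolution is pinned by
  the four printed cost figures below (pooled side 5 is the only small
  square for which the added conv MACs round to 0.003 G, and one bias
  vector is the only parameter budget that rounds to 0.136 M). We place the
  block after the depthwise stage's activation, mirroring where
  squeeze-excitation sits in related mobile blocks.
- **ECA block** after the projection BN: global average pool, a shared 1-D
  convolution of odd width k across channels (no bias), sigmoid gate. k is
  derived from the channel count as s = (log₂C + 1)/2, truncated and bumped
  to the next odd integer when even (so k = 3 up to C = 127, k = 5 for the
  160- and 320-channel stages; 59 weights in total).

HP totals 2,369,763 scalars (2.370 M); the delta over baseline is 135,643
(0.136 M).

Weights initialise Kaiming-normal (fan-out) for convolutions, (γ, β) = (1, 0)
for BN (eps 1e-5, momentum 0.1), and N(0, 0.01) for the classifier.

## Cost profiler

Parameters and FLOPs follow the closed forms for (grouped) convolutions:
params = K²·(C_in/G)·C_out (+C_out with bias), MACs = params·H_out·W_out;
G = 1 is a standard conv and G = C_in depthwise. The profiler enumerates a
built model's learnable scalars (these always agree with the closed forms)
and sums MACs from recorded output geometry.

FLOP totals depend on which auxiliary layers a profiler charges for. One
switch, calibrated once on the baseline and applied unchanged to every
variant, defines this package's convention: conv/linear MACs plus **4
operations per batch-norm output element** (the unfused subtract / divide /
scale / shift), with activations, pooling and elementwise gates free. Under
it the baseline reports 0.326 G at 224 × 224 and HP reports 0.329 G; the
conv-MAC delta (the DMS and ECA convolutions, 3.22 M MACs) independently
rounds to 0.003 G.

## Training

Published recipe: 224 × 224 input, 100 epochs, SGD, batch 64, and the
"95-Gradient" schedule — lr(e) = 0.01 · 0.95^⌊e/2⌋, stepwise-constant inside
each 2-epoch window. Momentum (default 0.9) and weight decay (default 0) are
not part of the published recipe; they are exposed in `TrainConfig` and
logged with every run. Softmax precedes the cross-entropy
L = −Σ y_c log p_c, with probabilities clamped at 1e-12. Best checkpoint =
highest validation accuracy, ties broken by lower validation loss. The loop
is fully seeded and aborts with a diagnostic on a non-finite loss.

The network, its layers and backpropagation are implemented on numpy inside
the package (`mungseed.nn`): im2col/matmul convolutions with a dedicated
einsum path for depthwise layers, standard batch-norm backward, and manual
adjoints for the attention blocks. Every layer's backward pass is verified
against central differences in the test suite.

### Problem sizes used in the test suite

Desk-scale runs exercise the same code paths at reduced size, a deliberate
choice for a CPU-only workflow: the smoke-training task uses the `small`
network preset (stem 16, stages (1,16,1,1), (6,24,2,2), (6,32,2,2), head
128 — same bottleneck/DMS/ECA wiring as the full model) at 32 × 32 input on
640 synthetic images (80 per class, split 512/64/64), batch 32, momentum
0.5 for the short 5-epoch run. With the fixed seeds this reaches ≥ 96 %
validation accuracy at epoch 5. Cost figures (2.234 M / 2.370 M / 0.326 G /
0.329 G) are always measured on the full-size networks at 224 × 224.

## Evaluation

Confusion matrices are oriented rows = actual, columns = predicted.
Per-class accuracy, precision, recall and F1 are one-vs-rest
((TP+TN)/total, TP/(TP+FP), TP/(TP+FN), 2TP/(2TP+FP+FN)); "Avg" figures are
unweighted (macro) means. A class with a zero denominator reports 0 and is
flagged rather than dropped, keeping the report schema stable. F1 always
lies between min(P, R) and max(P, R).

Grad-CAM: channel weights are the spatial means of the target logit's
gradient at a chosen feature layer (default: the last bottleneck's output);
the heatmap is the rectified weighted sum of feature maps, min–max
normalised to [0, 1] and upsampled bilinearly to input resolution. A
constant feature map (e.g. zero input through a bias-free stem) degenerates
to a flat zero map by convention.

## Configuration and reproducibility

Pipeline configs are YAML; unknown keys are hard errors, and every run
writes its resolved config next to its artifacts. One global seed fans out
to per-stage seeds via `(seed · 2654435761 + crc32(stage)) mod 2^31`.
Re-running any stage with the same config and seed reproduces its manifests
byte for byte.

## Known limitations

- Synthetic classes are hue-separable by design; results on them say
  nothing about accuracy attainable on real seed photographs.
- Training at the published scale (34,890 images, 100 epochs, 224 × 224) is
  far outside a single-CPU numpy budget; the harness is exercised at
  reduced scale.
- The profiler's FLOP figure is convention-dependent, as all such figures
  are; only the documented convention above is calibrated.
- Serialized checkpoint size is not modelled; it depends on the container
  format and dtype, not on the parameter count alone.
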