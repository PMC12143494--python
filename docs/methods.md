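# Methods

## Model

The segmentation network is a 2-D hybrid encoder–decoder. The encoder is a
stack of `len(conv_channels)` convolutional stages (3×3 conv, stride 2,
instance normalisation, ReLU), followed by a patch embedding (a strided
`patch_size`×`patch_size` convolution over the final feature map), a
learned positional embedding of length equal to the token count, and
`n_layers` pre-norm transformer blocks (multi-head self-attention with
separate Q/K/V projections, then a GELU MLP, each with a residual
connection), closed by a final layer norm. The token grid has side
`input_size / 2^stages / patch_size`. The decoder reshapes the tokens back
to a spatial grid, applies a 3×3 projection, and runs
`len(conv_channels) + log2(patch_size)` stages of 2× nearest-neighbour
upsampling + 3×3 conv, concatenating the encoder skip feature whenever the
running resolution matches one. Two heads share the decoder: a 3×3
single-channel reconstruction head and a 1×1 `n_classes` segmentation
head. Binary problems use `n_classes = 2` with softmax so binary and
multiclass share one code path.

Every parameter belongs to exactly one of four families — `conv_encoder`,
`transformer` (patch embedding, positional embedding, blocks, final norm),
`decoder`, `head` — assigned by name prefix; the partition is the unit of
transfer and freezing and is verified by test.

Normalisation choice: the convolutional stages use instance normalisation
(per sample, per channel over space) rather than batch normalisation. With
desk-scale batches of 2–4, batch statistics are noisy and introduce a
train/eval discrepancy through running means; instance norm has neither
problem and keeps every forward pass deterministic.

The numerical core is `retina_em.nn`, a small tape-based reverse-mode
autodiff engine on float32 numpy arrays (convolution as a sum of strided
einsums over kernel offsets, fused softmax/log-softmax/layer-norm
backward, broadcast-aware batched matmul). Every operation's gradient is
tested against central differences.

## Pre-training objective

One clean patch produces a pair: target = geometric(x), input =
corrupt(geometric(x)). The loss is the plain mean squared error between
the reconstruction and the target over all pixels, including masked
patches — the masked regions make the objective partly an inpainting
problem, which forces the deep layers to be used rather than letting skip
connections shortcut the task.

The geometric set (applied to both images) is horizontal flip, vertical
flip (each with probability 0.5) and a counter-clockwise rotation by a
right angle (with probability 0.5, the quarter-turn count uniform on
{1,2,3}). Right-angle rotations keep the transform exactly invertible with
no interpolation, which is what makes the pair-alignment guarantee exact.

The corruption set (applied to the input only), in fixed order
brightness/contrast → noise → blur → clip to [0,1] → patch masking:

| operation | probability | parameter default | units |
|---|---|---|---|
| brightness shift | 0.5 | U(−0.2, 0.2) | intensity |
| contrast gain (about mid-grey 0.5) | 0.5 | U(0.8, 1.2) | multiplier |
| Gaussian noise | 0.5 | sd ~ U(0, 0.05) | intensity |
| Gaussian blur | 0.5 | sd ~ U(0, 1.5) | pixels |
| patch masking | 1.0 | count uniform on 1–32, 16 px patches, fill 0 | — |

These parameter values are artifact defaults (all configurable); the
probabilities of the geometric operations and the 1–32 masked-patch range
are fixed by the method. Sampled records (including the noise seed) are
JSON-serialisable, so any pair can be replayed bit-exactly.

## Training

Optimizer: SGD with momentum 0.9 and polynomial per-iteration decay
`lr_t = lr0 (1 − t/T)^0.9`; one iteration is one batch-level update.
Fine-tuning loss: equally weighted pixel-wise cross-entropy + soft Dice
over all classes (`ce_dice`; plain `ce` available). The Dice term
mitigates foreground/background imbalance, so no class re-weighting is
applied. Fine-tuning applies flips/right-angle-rotation augmentation to
image and label jointly (toggle `augment_finetune`).

Transfer copies the transformer family bit-exactly from a checkpoint into
the target model and touches nothing else; freezing removes a family from
the optimizer's update set, so frozen arrays are bit-identical after any
number of steps (both properties are asserted, not approximated). The
default fine-tuning policy freezes only the transformer: the convolutional
layers stay free to adapt local feature extraction to the labeled dataset
while the globally pre-trained attention layers are preserved.

All randomness (batch sampling, augmentation, initialisation) flows from
explicit integer seeds; runs are reproducible to the bit in a fixed
environment.

## Inference

Volumes use axis order (z, y, x); the TIFF page axis is z. Slices are
covered with non-overlapping tiles of the model input size and stitched;
border tiles are reflection-padded (repeating the reflection when a slice
is smaller than half a tile). Tiling avoids the label-space interpolation
artifacts that rescaling would introduce. Orthoplane inference averages
the three plane-wise softmax probability volumes voxel-for-voxel —
averaging probabilities (not logits) keeps the result a distribution — and
is intended for isotropic volumes; for anisotropic volumes (z spacing >
xy spacing) only xy prediction is meaningful and a warning is issued
otherwise. Argmax ties break toward the smaller class ID.

## Metrics

Ratio metrics come from per-class confusion counts: IoU = tp/(tp+fp+fn),
precision, recall, F = 2PR/(P+R). Distance metrics operate on foreground
voxel sets via the Euclidean distance transform with optional anisotropic
spacing: MFD is the mean of the two directed Hausdorff distances
(max-of-min in both directions); ADGT is the mean distance from predicted
foreground voxels to the nearest ground-truth voxel, ADF the reverse, and
the CREMI score their mean. The efficient distance-transform path is
checked against O(n²) brute-force pair loops in the tests.

Degenerate masks: empty/empty gives ratio metrics of 1.0 (perfect
agreement, avoids NaN poisoning of aggregates); one-sided-empty gives
ratio metrics by formula and distance metrics reported as missing
(`None`), never 0. Aggregation is an unweighted mean, either over
independent binary tasks or over the foreground classes of one multiclass
task (background excluded by default; `include_background` available).
MFD is reported per class and never averaged with ratio metrics.

## Synthetic data

The generator emulates the *geometry and value range* of EM patch data,
not its content statistics: background is Gaussian-blurred white noise
rescaled to [0.3, 0.7]; "organelles" are soft-edged axis-aligned ellipses/
ellipsoids with intensity offsets of ±[0.15, 0.30] (sign alternating by
class so classes are visually distinct), semi-axes 4–10 voxels, 2–4
objects per class by default. Later-drawn classes overwrite labels where
objects overlap. Anisotropy is modelled as metadata plus z-compressed
object shapes (no point-spread-function simulation) — sufficient to
exercise the xy-only inference logic. Default patch size is 224 px
(matching standard EM patch corpora); the test suite uses 64 px.

Consequently, passing tests demonstrate that the optimisation, transfer,
freezing, inference and metric machinery are correct and that the network
has the capacity to learn contrast-based segmentation; they say nothing
about segmentation accuracy on real micrographs, which depends on
large-scale pre-training and real labeled data.

## Problem sizes and numerical choices

The test suite and the acceptance script run a "tiny" configuration chosen
as the smallest network exercising every architectural element: input
64 px, conv channels (16, 32), patch size 2 (8×8 = 64 tokens), embed dim
32, 2 blocks, 2 heads, MLP 64, decoder (32, 16, 16). Pre-training
convergence is measured over 500 iterations of batch 4 on 8 images;
fine-tuning capacity over 300 iterations on one labeled image; the
generalisation run fine-tunes on 8 slices of a 10×64×64 volume and
evaluates on the held-out 2. Learning rate 0.05 for both phases at this
scale.

Other numerical choices: normalisation epsilon 1e-5; probability-volume
class sums hold to 1e-5; orthoplane identity to 1e-6 (float32 averaging);
soft-Dice smoothing 1e-6; GELU uses the tanh approximation.

## Known limitations

- 2-D only; no 3-D convolutions or attention.
- No sliding-window overlap or Gaussian blending at tile seams; tile
  borders can show minor discontinuities on large slices.
- Instance segmentation (and watershed-style post-processing) is out of
  scope; the pipeline is end-to-end semantic segmentation.
- The numpy engine is single-device and unsuited to corpus-scale
  pre-training; the architecture, not throughput, is the point.
- The synthetic generator's texture model is deliberately simple (see
  above); no membrane/neurite geometry.
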