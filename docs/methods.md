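# Methods

## Problem and model

Ischemic stroke lesions in MRI are small, diffuse and low-contrast; an
accurate segmenter must combine fine local detail with context far beyond a
standard convolution's receptive field. `strokeseg` implements an
encoder–decoder network that attacks this from three directions at once:
dense convolutional connectivity (feature reuse and fine detail), dilated
convolutions (wide context at no extra parameter cost), and decoder
self-attention (explicit long-range dependencies).

The network operates on single-modality 2‑D slices normalised to [0, 1].
Encoder: a stem (Conv3×3 → BN → ReLU, `stem_width` channels, resolution
unchanged), then three dilated dense blocks (DDBs) with transition layers
after the first two and a third transition in the bottleneck, then a center
DDB. Decoder: three stages of nearest-neighbour ×2 upsampling (with a
channel-halving 1×1 convolution), concatenation of the matching encoder
skip, a transformer block, and a DDB. A 1×1 convolution and sigmoid produce
the per-pixel lesion probability. Inputs must be divisible by 8 (three
halvings); odd intermediate sizes are rejected rather than padded so every
shape in the network is exactly reproducible.

### Dilated dense block

The dilated stack is three Conv3×3 → BN → ReLU layers at dilation rates
(2, 4, 8), all with `dilated_channels` outputs and same-padding. Its
unit-impulse response spans 1 + 2·(2+4+8) = 29 pixels per axis, which the
test-suite verifies numerically. The dense block then runs L = 4 layers of
BN → ReLU → Conv3×3 producing `growth` channels each, concatenated onto the
running stack (input first), with dropout 0.2 after each convolution;
output channels = input + L·growth. Placing the dense block after the
dilated stack lets the detail-preserving dense features inherit the
enlarged context.

Choices the architecture description leaves open, fixed here: the stem is a
single conv (all downsampling lives in transitions, and the stem keeps
resolution); the dilated stack uses Conv → BN → ReLU per layer; dense
layers use the pre-activation order BN → ReLU → Conv with dropout after the
convolution (DenseNet convention); transition layers are BN → ReLU →
Conv1×1 keeping a θ = 0.5 fraction of channels followed by a strided
Conv3×3 (the halving step); upsampling is nearest-neighbour ×2 plus a 1×1
convolution halving channels.

### Decoder transformer block

Each decoder stage tokenises its feature map into non-overlapping
`patch × patch` tiles (schedule 1/2/4 from coarse to fine, so every stage
sees the same token count — 2,304 tokens at the 192×192 working
resolution), embeds tokens linearly to a fixed width `embed_dim`, adds a
sinusoidal positional encoding, and applies one post-norm transformer
encoder layer — MHSA with n = 4 heads and scaled dot-product scores
(softmax of Q_i K_iᵀ/√d_h, rows summing to 1), Add & Norm, position-wise
FFN (two linear layers with an inner ReLU, width `ffn_dim`), Add & Norm —
then un-embeds and re-assembles the map. Pre-norm placement is available as
a config switch; post-norm is the default.

The fixed-width embedding is a deliberate design choice. Without it the
attention dimensionality would be the stage's channels × patch², which
grows 16-fold across the decoder; under the batch-norm budget below no
width schedule can then land on the reference parameter count while
remaining trainable on a desk machine. A shared `embed_dim` decouples
attention capacity from stage geometry, keeps all three stages' attention
cost identical, and makes the calibration solvable exactly.

### Weight initialisation

All convolution and linear weights are He-normal: zero-mean normal with
σ = √(2/m) for fan-in m, truncated at ±2σ (sampled exactly via the inverse
normal CDF, so draws are bit-reproducible per seed). Biases start at zero,
BN at γ = 1, β = 0. The Monte-Carlo test checks the sample moments against
the truncated normal's closed-form standard deviation (≈ 0.8796 σ).

## Parameter calibration

The reference budget is 13,662,913 parameters: 13,649,473 trainable and
13,440 non-trainable. Non-trainable parameters are interpreted as the
batch-norm running mean and variance — two per BN channel — so the BN
channel widths must sum to exactly 6,720. For this topology that sum is
`stem + 52·dilated + 54·growth` (7 DDBs at 7·dilated + 6·growth each, plus
three transitions at dilated + 4·growth). The bias convention matters to
the count and is fixed as: convolutions immediately followed by BN carry no
bias; every other convolution and all linear layers do.

`scripts/calibrate_widths.py` enumerates integer schedules on the BN
constraint and solves the trainable constraint in closed form — the count
is linear in `ffn_dim`, so each candidate either divides exactly or is
discarded. Five exact schedules exist in the searched range; the shipped
default (stem 82, dilated 110, growth 17, embed 260, ffn 4057) is the one
with the lowest estimated forward cost, and the script re-verifies it by
building the model and re-counting. Nothing in the triple is asserted by
fiat: `scripts/acceptance.py` recomputes it by walking the instantiated
layer list.

## Ablation variants

The factory exposes five configurations through two flags and a block
style: the flagship (dilated + dense + transformer), transformer dense
U-Net (no dilated stack), dilated dense U-Net (no transformer), dense U-Net
(neither), and transformer U-Net (plain double-conv blocks of the DDB's
output width, transformer retained). Removing the transformer changes
nothing else — the blocks are shape-preserving — so the flagship minus its
attention parameters equals the dilated dense U-Net exactly; removing the
dilated stacks shifts downstream widths, and the factory is checked
name-by-name to leave no dangling weights.

## Losses and metrics

BCE is the standard two-term form, mean-reduced, with probabilities clipped
at ε = 10⁻⁷; the Dice loss is the soft form 1 − (2Σyp + s)/(Σy + Σp + s)
with smoothing s = 1 (which also defines the empty-mask case as zero loss);
sigmoid-BCE operates on logits in the log-sum-exp stable form; BCE-Dice is
their unit-weight sum and the default training loss. Mean (not sum)
reduction keeps loss magnitudes batch-size independent — if a reference
recipe used sum reduction its learning rate would not transfer directly.
The evaluation Dice coefficient is the hard-count form 2TP/(2TP+FP+FN)
(defined as 1 when both masks are empty); accuracy is (TP+TN)/M.

## Preprocessing pipeline

Volumes load from NIfTI through nibabel and are normalised to depth-major
axis order. Per subject: slices are extracted axially; blank slices are
trimmed from both ends only (a slice is blank when under 2% of its pixels
exceed 1% of the slice maximum — the trimming criterion is never quantified
in reference descriptions, so it is exposed in the config); images are
resized to 192×192 bilinearly and masks with nearest-neighbour so they stay
binary; intensities are min–max scaled per slice (a constant slice maps to
zeros). Augmentation expands the set by an exact integer factor (default
3): originals plus factor−1 copies, each with one transform drawn uniformly
from horizontal flip, zoom in [0.9, 1.1], shear up to 10°, or rotation in
[0°, 90°], applied identically to image and mask with mask re-binarisation.
Only the rotation interval is prescribed by the reference recipe; zoom and
shear ranges are conservative choices. The train/validation split is a
seeded shuffle with an 80/20 partition; the CLI splits by subject by
default to avoid slice leakage between partitions.

## Synthetic phantoms

The generator emulates the reference acquisition geometry: 153 slices of
230×230 voxels at 1 mm spacing, with 46 blank slices at each end so that 64
subjects trim to 64 × 61 ≈ 3,900 usable slices (matching the documented
data reduction, and ×3 augmentation ≈ 11,700). Each phantom is an
elliptical brain with low-frequency texture (background 0.3 ± 0.1), one to
three spherical-ish lesions of 4–20 px radius whose blurred intensity boost
(+0.4) is below the texture + noise spread — so naive thresholding does not
solve the task and a learning test is meaningful (the suite checks the best
global threshold stays below Dice 0.98). Phantoms are 2‑D-stacked ellipses,
not anatomy: passing tests demonstrate that the pipeline, optimisation and
metrics behave correctly, not that the model reaches clinical accuracy on
patient data — that requires the gated challenge datasets and GPU-scale
training, which are outside this package's scope.

## Numerical and engineering choices

The network runs on `strokeseg.nn`, a compact reverse-mode autodiff engine
over NumPy arrays (float32 forward/backward; BLAS matmuls via a
shifted-slice convolution that avoids materialising im2col buffers).
Gradients of every primitive are verified against central finite
differences in the test-suite. BN uses momentum 0.99 and eps 10⁻³;
LayerNorm eps 10⁻⁵; Adam uses β = (0.9, 0.999), eps 10⁻⁷. Binarisation uses
a strict `p > t` rule (an all-0.5 map thresholds to background).
Determinism: model seeds fix initialisation and dropout; the training seed
fixes shuffling; phantom seeds fix data — identical seeds reproduce runs
bit-for-bit on the same platform.

Problem sizes in the test-suite are chosen for a desk machine: structural
tests run a miniature width schedule; the learning smoke tests run the
full-width flagship on one 64×64 pair (overfitting to Dice > 0.9, typically
in ~20 steps at learning rate 10⁻³) and on twenty 32×32 pairs for five
epochs per loss. A full-resolution 192×192 forward pass of the flagship
takes well under 30 s on one CPU core.

## Known limitations

* Single-modality 2‑D slices only; no multimodal fusion, no 3‑D context.
* The phantom generator does not simulate modality-specific contrast
  (DWI vs FLAIR appearance) or guarantee 3‑D lesion continuity.
* Reference accuracy on clinical datasets is not reproduced here (data are
  gated and training is GPU-scale); the package's claims are the exact
  parameter budget, the pipeline's counting behaviour, and the learning
  dynamics at smoke scale.
* Attention memory grows quadratically in token count; the patch schedule
  caps tokens at 2,304 per stage at 192×192, and larger inputs require
  coarser patches.
* No early stopping or learning-rate schedules by default (fixed-epoch
  training per the reference recipe); both can be added around
  `train_model` if needed.
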