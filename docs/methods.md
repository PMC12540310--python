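# Methods

## Model

MAUNet is a 3D encoder–decoder operating on four co-registered MRI
modalities (T1, T1ce, T2, FLAIR) stacked as input channels, producing
three sigmoid probability channels for the nested evaluation regions
WT ⊇ TC ⊇ ET. Arrays are channel-first `(C, D, H, W)` without a batch
axis; training uses single-volume batches, so instance normalization
(per-channel spatial statistics, affine rescale, eps 1e-5) follows every
convolution — batch statistics would be degenerate at batch size 1.

Stage layout for `base_width` w (default 32):

| stage | operation | width |
|---|---|---|
| stem | 5×5×5 conv, pad 2 | 4 → w |
| encoder ×3 | SMDConv (two 3×3×3 conv blocks + SMWA), then 2× max-pool | w, 2w, 4w |
| bottleneck | dilated 3×3×3 conv (rate 2) → CFC → dilated conv (rate 4) → CFC | 8w |
| decoder ×3 | trilinear 2× upsampling, gated fusion with the matching skip, SMDConv | 4w, 2w, w |
| head | 1×1×1 conv + sigmoid | w → 3 |

Each attention family (SMWA, CFC, skip gates) is independently
switchable; a disabled family contributes no parameters, so the ablation
lattice from the plain double-conv baseline to the full model is a chain
of strict subnetworks.

### SMWA

Channel attention uses one MLP (C → max(C/r, 1) → C, rectifier between,
r = 4) shared between the global average- and max-pooled descriptors;
the sigmoid of the summed outputs scales each channel. Each of the
three axis branches compresses the channel-attended field to per-slice
average and maximum descriptors along its axis, mixes k = 3
neighbouring slices of the two stacked descriptors with one k×2 kernel
into a logit per slice, applies a sigmoid, and scales its reweighted
field by a learnable scalar initialized at 1. The descriptor
convolution uses replicate (edge) padding: it preserves the slice count
and keeps an axis-constant field mapping to equal slice weights, which
zero padding would break at the edges. The three branch outputs are
summed.

### CFC

A 1×1×1 conv halves the channel count (C′ = C/2) to form the query
field Q. Cascaded pyramid pooling applies adaptive max pooling to grids
5³ → 3³ → 1³, each stage pooling the previous stage's output; all
pooled cells form the context matrix Z (C′ × M, M = 153 at full size;
grids clamp per-axis on smaller bottlenecks). Linear maps give keys
K (C′ × M) and values V (C × M). Affinity is the per-voxel softmax over
cosine similarities between Q vectors and keys (a raw-dot-product
variant is available by flag); cosine keeps the logits in [−1, 1],
which stabilizes the softmax regardless of feature scale. Zero-norm
vectors are handled by an epsilon (1e-8) inside the norm, which also
keeps the gradient finite. The aggregated context E = V·Aᵀ is a convex
combination of value columns per voxel. Recalibration multiplies E by
1 + tanh(W₂(W₁(X+E))) — a factor in (0, 2), so context can be damped or
amplified but never sign-flipped — and the result is added residually.

### Gated skips

The skip and upsampled decoder tensors are concatenated; a two-layer
MLP (r = 4) on the global-average channel descriptor followed by a
sigmoid yields one retention weight per channel of the concatenation.
Gating the concatenated stack (rather than the skip alone) keeps the
mechanism a pure add-on: disabling it degrades exactly to plain
concatenation.

## Loss and metrics

The loss is α·BCE + β·soft-Dice with α = 1, β = 0.5, averaged over the
three region channels. Soft Dice adds ε = 1e-5 to numerator and
denominator for differentiability and empty-mask stability; BCE clamps
probabilities at 1e-7. Labels follow the BraTS integer convention
(0 background, 1 necrotic core, 2 edema, 4 enhancing tumor); regions are
WT = NCR∪ED∪ET, TC = NCR∪ET, ET. Metrics are computed from exact voxel
confusion counts; a ratio with vanishing denominator scores 1.0 when
prediction and reference are both empty, else 0.0. Specificity is
TN/(TN+FP); a nonstandard TN/(TP+FP) variant is retained behind
`printed_specificity=True` for comparability with reports that use it.

## Data pipeline

Scanner-geometry volumes (155×240×240) are z-scored per modality over
nonzero (brain) voxels only — background stays exactly zero — then the
depth axis is zero-padded to 160 (2 slices before, 3 after; padding
rather than interpolation preserves label crispness and voxel
provenance), which splits into five contiguous 32-slice segments. The
240×240 plane is handled by 128×128 windows: during training a random
crop, biased 50% toward tumor-containing positions to counter class
imbalance; at inference a sliding-window cover (stride 112) whose
overlapping probabilities are averaged, so every voxel is predicted.
Random flips during training apply the identical axis choices to image
and label. All randomness fans out from a single integer seed
(default 41) through separate spawned streams for initialization,
splitting, cropping and flipping, so runs are bit-reproducible on CPU.

## Synthetic phantoms

A phantom is an ellipsoidal brain of nonzero intensity on a zero
background containing three concentric spherical compartments (ET
inside NCR inside ED), with the tumor center drawn uniformly inside the
margin that keeps the lesion in-brain. Intensities are per-tissue means
(FLAIR bright over edema, T1ce bright over enhancing tumor, T2 bright
over the lesion, T1 near-isointense — qualitative contrast folklore
encoded as an editable table) plus Gaussian noise, sd 0.1 against
tissue means of order 1. Default grid 155×240×240; the `tiny` preset
uses 32×64×64 with proportionally larger radius fractions
(0.30/0.19/0.11) so all compartments stay several voxels wide.

The phantoms exercise geometry, nesting, class imbalance and the full
I/O path, and their simple deterministic contrast makes them learnable
by a very small network in minutes. They do not emulate MRI physics,
bias fields, lesion texture, anatomical variability or ambiguous
boundaries — passing the learnability check therefore validates the
architecture, loss and pipeline plumbing, not clinical-grade accuracy.

## Training

Adam (default lr 1e-4, the reference protocol), batch size 1, 100
epochs, early stopping on validation mean Dice with patience 10, 80/20
case split, best-checkpoint retention. The `tiny` preset — base_width
8, float32, 16×32×32 training crops, lr 3e-3, 30 epochs — exists for
desk-scale runs: a few hundred steps of a small network on easy
geometry need a step size well above the full-scale protocol's to
converge within the schedule. Checkpoints are .npz archives embedding
the architecture config and a version tag.

## Numerical choices

* The compute layer (`maunet.nn`) is a tape-based reverse-mode autodiff
  over numpy; convolutions evaluate as shift-and-accumulate over kernel
  taps (one BLAS matmul per tap), keeping memory at one padded copy.
  All primitives are verified against central finite differences.
* Max-reduction gradients split evenly among tied argmax positions.
* Trilinear upsampling uses half-pixel centers with edge clamping;
  per-axis interpolation matrices make the adjoint exact.
* Float64 is the default for block-level work; the network presets use
  float32. Oracle comparisons in the tests run in float64 at 1e-5.
* Parameter init: Kaiming-style normal scaled by fan-in; biases zero;
  SMWA branch scales 1.0, making the untrained block a plain
  mixed-attention pass.

## Scale of the shipped experiments

The test suite and the acceptance script run entirely on synthetic
phantoms at the tiny preset: 4 training cases of 32×64×64, ≤300
optimization steps, evaluation by full-grid sliding-window prediction.
Because a few-hundred-step schedule is seed-sensitive (the smallest
compartment occasionally stays unfit), learnability is judged over
three seeds — the tests require 2 of 3 to reach mean training Dice
0.90, and the acceptance script scores the median-seed run. These
sizes were chosen so the whole study re-runs from scratch in minutes
on one CPU core while still exercising every architectural component
at full depth (three resolution levels, both CFC blocks, all gates).

## Known limitations

* No GPU path; full-scale (base_width 32, 155×240×240) training is out
  of reach of the numpy engine — forward passes work, but a full
  training protocol would take days on CPU.
* Batch size is structurally 1 (no batch axis).
* The flip-equivariance and augmentation-consistency checks hold for
  palindromic kernels only — a convolution with arbitrary kernels is
  not flip-equivariant — so the tests symmetrize kernels to isolate the
  architectural claim (no asymmetry from padding, pooling, upsampling).
* Axis-attention interprets the (1,1,k) descriptor convolution as one
  joint k×2 kernel over the stacked (avg, max) descriptors; separate
  kernels per descriptor would be an equally defensible reading.
* Hausdorff/surface metrics, deep supervision, test-time augmentation
  and attention-map export are out of scope.
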