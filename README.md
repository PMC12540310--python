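# maunet

Multi-attention 3D U-Net for segmenting the nested tumor regions of
multimodal brain MRI — whole tumor (WT), tumor core (TC) and enhancing
tumor (ET) — together with a synthetic phantom generator so the entire
train/predict/evaluate workflow runs on a laptop with no external data.

The package is aimed at researchers in medical image analysis who want a
fully inspectable, dependency-light reference implementation of an
attention-augmented volumetric segmentation network: every layer, the
training loop and the optimizers run on a small numpy reverse-mode
autodiff engine shipped inside the package (`maunet.nn`).

## The model

MAUNet is a 3D encoder–decoder with three attention families on top of a
double-conv U-Net baseline:

* **SMWA** (spatial multi-dimensional weighted attention), inside every
  encoder/decoder conv stage: channel attention
  `f_c = sigmoid(MLP(avgpool f) + MLP(maxpool f)) ⊗ f`
  followed by three per-axis branches that compress `f_c` to per-slice
  (avg, max) descriptors along D, H and W, convolve them with a (1,1,k)
  kernel into one logit per slice, and fuse the sigmoid-weighted results
  with learnable scalars: `f_s = W₀·f_sd + W₁·f_sh + W₂·f_sw`.
* **CFC** (contextual feature calibration), twice in the dilated-conv
  bottleneck: cascaded pyramid max-pooling extracts M multi-scale
  contexts Z from a reduced query field Q; a row-stochastic affinity
  `A_ij = softmax_j(cos(Q_i, K_j))` soft-assigns every voxel to the
  contexts; the aggregated context `E = V·Aᵀ` is recalibrated by a tanh
  gate, `E' = tanh(W₂(W₁(X+E)))⊙E + E`, and added back, `Y = X + E'`.
* **Gated skip connections**: each skip/decoder concatenation is
  reweighted per channel by `sigmoid(MLP(avgpool))` before the decoder
  convs, softly suppressing redundant features.

Training minimizes `l = α·l_bce + β·l_dice` (α = 1, β = 0.5) over the
three sigmoid region channels; evaluation reports Dice, sensitivity,
specificity and precision per region from exact voxel confusion counts.

## Worked example

```bash
# 1. four synthetic phantoms (nested ET ⊆ TC ⊆ WT ellipsoids, 32×64×64)
maunet synth --out-dir data --n-cases 4 --seed 41 --preset tiny

# 2. train the tiny preset (base_width 8, lr 3e-3, ~300 steps)
maunet train --manifest data/manifest.csv --out-dir run --preset tiny --seed 41

# 3. predict and score
maunet predict --checkpoint run/checkpoint.npz --manifest data/manifest.csv \
               --out-dir preds --preset tiny
maunet evaluate --pred-dir preds --manifest data/manifest.csv --out metrics.csv
```

The training log streams one JSON record per epoch; this run prints

```
{"epoch": 0, "step": 12, "train_loss": 1.0279971566391002, "val_dice": 0.3012649520675859}
...
{"epoch": 29, "step": 360, "train_loss": 0.06288079401130921, "val_dice": 0.9353422208031543}
finished after 360 steps; best validation mean Dice 0.9414
```

where `train_loss` is the epoch-mean compound loss and `val_dice` the
mean WT/TC/ET Dice of thresholded sliding-window predictions on the
held-out split. `evaluate` then prints per-region means in percent:

```
WT: Dice 93.1%  Sensitivity 100.0%  Specificity 99.6%  Precision 87.1%
TC: Dice 93.5%  Sensitivity 99.8%  Specificity 99.9%  Precision 88.0%
ET: Dice 96.2%  Sensitivity 98.5%  Specificity 100.0%  Precision 93.9%
```

A converged tiny model sits in the 90s for all regions on phantoms; a
low ET score usually means the run stopped before the smallest
compartment was fit.

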