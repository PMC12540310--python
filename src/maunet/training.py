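"""Training, prediction and evaluation loops.

Single-volume batches (batch size 1), Adam by default at the reference
learning rate, random-crop + random-flip augmentation, validation by
sliding-window prediction, early stopping on validation mean Dice.
A single integer seed fans out deterministically to parameter
initialization, the train/validation split, crop sampling and flips.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .data_pipeline import (LabelVolume, MultimodalVolume, PatchSpec,
                            extract_patches, inference_patches, load_case,
                            manifest_row_paths, normalize, pad_depth,
                            random_flip, read_manifest, assemble_prediction)
from .losses_metrics import (LossWeights, combined_loss, encode_regions,
                             region_metrics)
from .network import MAUNet, NetworkConfig, save_checkpoint
from .nn.optim import OPTIMIZERS


@dataclasses.dataclass
class RunConfig:
    """Run hyperparameters; defaults follow the reference protocol."""

    lr: float = 1e-4
    optimizer: str = "adam"
    batch_size: int = 1
    epochs: int = 100
    seed: int = 41
    early_stopping_patience: int = 10
    alpha: float = 1.0
    beta: float = 0.5
    val_fraction: float = 0.2
    patches_per_case: int = 1
    max_steps: int | None = None
    validate_every: int = 1
    threshold: float = 0.5
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    train_patches: PatchSpec = dataclasses.field(default_factory=PatchSpec)
    eval_patches: PatchSpec = dataclasses.field(
        default_factory=lambda: PatchSpec(sampling="sliding-window"))

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}; "
                             f"choose from {sorted(OPTIMIZERS)}")

    @classmethod
    def tiny(cls, **kw) -> "RunConfig":
        """Desk-scale preset: base_width-8 net, 32×64×64 phantom grids.

        The short schedule uses a larger step size (3e-3) than the
        full-scale protocol; small nets on easy geometry underfit badly
        at 1e-4 within a few hundred steps.
        """
        kw.setdefault("lr", 3e-3)
        kw.setdefault("epochs", 30)
        kw.setdefault("patches_per_case", 2)
        kw.setdefault("network", NetworkConfig(base_width=8, dtype="float32"))
        kw.setdefault("train_patches",
                      PatchSpec(depth_chunk=16, inplane=32, depth_target=32, stride=32))
        kw.setdefault("eval_patches",
                      PatchSpec(depth_chunk=32, inplane=64, depth_target=32,
                                sampling="sliding-window", stride=32))
        return cls(**kw)

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x
        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig(**d["network"])
        for key in ("train_patches", "eval_patches"):
            if key in d and isinstance(d[key], dict):
                d[key] = PatchSpec(**d[key])
        return cls(**d)


@dataclasses.dataclass
class CaseData:
    case_id: str
    volume: MultimodalVolume
    label: LabelVolume | None


def load_cohort(manifest_path, pad_to_standard: bool = True) -> list[CaseData]:
    """Load, normalize and (when in scanner geometry) depth-pad all cases."""
    df = read_manifest(manifest_path)
    if not len(df):
        raise ValueError(f"manifest {manifest_path} lists no cases")
    cases = []
    for _, row in df.iterrows():
        volume, label = load_case(manifest_row_paths(row))
        volume = normalize(volume)
        if pad_to_standard and volume.shape[1] == 155:
            volume, label = pad_depth(volume, label)
        cases.append(CaseData(str(row["case_id"]), volume, label))
    return cases


def split_cases(cases: list[CaseData], val_fraction: float,
                rng: np.random.Generator) -> tuple[list[CaseData], list[CaseData]]:
    idx = rng.permutation(len(cases))
    if val_fraction <= 0 or len(cases) < 2:
        n_val = 0
    else:
        n_val = max(1, int(round(val_fraction * len(cases))))
    val_idx = set(idx[:n_val].tolist())
    train = [c for i, c in enumerate(cases) if i not in val_idx]
    val = [c for i, c in enumerate(cases) if i in val_idx]
    return train, val


def predict_volume(net: MAUNet, volume: MultimodalVolume, spec: PatchSpec) -> np.ndarray:
    """Full-grid region probabilities via sliding-window assembly."""
    patches = inference_patches(volume, spec)
    preds = [net.predict(p.image) for p in patches]
    return assemble_prediction(preds, [p.offset for p in patches],
                               volume.shape[1:])


def evaluate_cases(net: MAUNet, cases: list[CaseData], spec: PatchSpec,
                   threshold: float = 0.5) -> dict[str, dict[str, dict[str, float]]]:
    """Per-case per-region metrics on thresholded sliding-window predictions."""
    out = {}
    for case in cases:
        probs = predict_volume(net, case.volume, spec)
        target = encode_regions(case.label.labels)
        out[case.case_id] = region_metrics((probs > threshold).astype(np.uint8), target)
    return out


def mean_region_dice(per_case: dict) -> float:
    vals = [m["dice"] for regions in per_case.values() for m in regions.values()]
    return float(np.mean(vals)) if vals else float("nan")


@dataclasses.dataclass
class TrainResult:
    net: MAUNet
    log: list[dict]
    best_val_dice: float
    best_state: dict
    steps: int


def train(cases: list[CaseData], cfg: RunConfig,
          out_dir=None, log_hook=None) -> TrainResult:
    """Fit a network on the given cases.

    Writes (when ``out_dir`` is set) the best checkpoint, a JSONL training
    log, and a resolved-config snapshot.
    """
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, split_ss, crop_ss, flip_ss = ss.spawn(4)
    net = MAUNet(cfg.network, np.random.default_rng(init_ss))
    split_rng = np.random.default_rng(split_ss)
    crop_rng = np.random.default_rng(crop_ss)
    flip_rng = np.random.default_rng(flip_ss)

    train_cases, val_cases = split_cases(cases, cfg.val_fraction, split_rng)
    if not train_cases:
        raise ValueError("no training cases after split")
    weights = LossWeights(cfg.alpha, cfg.beta)
    opt = OPTIMIZERS[cfg.optimizer](net.parameters(), lr=cfg.lr)

    log: list[dict] = []
    best_val = -np.inf
    best_state = net.state_dict()
    stale = 0
    steps = 0
    stop = False
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for case in train_cases:
            for _ in range(cfg.patches_per_case):
                patches = extract_patches(case.volume, case.label,
                                          cfg.train_patches, crop_rng)
                for patch in patches:
                    patch, _axes = random_flip(patch, flip_rng)
                    pred = net(patch.image)
                    target = encode_regions(patch.label).stack()
                    loss = combined_loss(pred, target, weights)
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    epoch_losses.append(loss.item())
                    steps += 1
                    if cfg.max_steps is not None and steps >= cfg.max_steps:
                        stop = True
                        break
                if stop:
                    break
            if stop:
                break
        record = {"epoch": epoch, "step": steps,
                  "train_loss": float(np.mean(epoch_losses)) if epoch_losses else None}
        if val_cases and (epoch % cfg.validate_every == 0 or stop):
            per_case = evaluate_cases(net, val_cases, cfg.eval_patches, cfg.threshold)
            record["val_dice"] = mean_region_dice(per_case)
            if record["val_dice"] > best_val:
                best_val = record["val_dice"]
                best_state = net.state_dict()
                stale = 0
            else:
                stale += 1
        log.append(record)
        if log_hook:
            log_hook(record)
        if stop or (val_cases and stale >= cfg.early_stopping_patience):
            break
    if not val_cases:
        best_state = net.state_dict()
    net.load_state_dict(best_state)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "checkpoint.npz", net,
                        extra={"best_val_dice": float(best_val), "steps": steps})
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
    return TrainResult(net, log, float(best_val), best_state, steps)
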