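"""I/O and preprocessing for multimodal volumes.

Coordinate convention: arrays are (modality, depth, height, width) with
0-based, half-open windows.  Scanner-geometry volumes arrive as
155 × 240 × 240; the depth axis is zero-padded to 160 so it splits into
five contiguous 32-slice chunks, and the 240 × 240 plane is handled by
128 × 128 windows — a random (tumor-biased) crop during training and an
overlap-averaged sliding-window cover at inference.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .losses_metrics import VALID_LABELS
from .synthetic_phantoms import MODALITIES

NORM_EPS = 1e-8


@dataclasses.dataclass
class MultimodalVolume:
    intensities: np.ndarray          # (4, Dz, Hy, Wx)
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4 or self.intensities.shape[0] != len(MODALITIES):
            raise ValueError(f"expected ({len(MODALITIES)}, D, H, W), got {self.intensities.shape}")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")

    @property
    def shape(self):
        return self.intensities.shape


@dataclasses.dataclass
class LabelVolume:
    labels: np.ndarray               # (Dz, Hy, Wx) integer compartments
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown label values {sorted(bad)}")


@dataclasses.dataclass
class PatchSpec:
    depth_chunk: int = 32
    inplane: int = 128
    depth_target: int = 160
    sampling: str = "random-crop"    # grid | random-crop | sliding-window
    stride: int = 112                # in-plane stride for sliding windows
    tumor_bias: float = 0.5          # fraction of random crops centered on tumor

    def __post_init__(self):
        if self.depth_target % self.depth_chunk:
            raise ValueError(
                f"depth_target {self.depth_target} not divisible by chunk {self.depth_chunk}")
        if self.sampling not in ("grid", "random-crop", "sliding-window"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.stride > self.inplane:
            raise ValueError("stride larger than window leaves coverage gaps")


@dataclasses.dataclass
class Patch:
    image: np.ndarray                # (4, dz, hy, wx)
    label: np.ndarray | None         # (dz, hy, wx) or None at inference
    offset: tuple[int, int, int]     # (z0, y0, x0) placement in the padded grid


# -- case I/O ----------------------------------------------------------------

def load_case(paths: dict[str, str]) -> tuple[MultimodalVolume, LabelVolume | None]:
    """Load one case from per-modality NIfTI paths.

    ``paths`` maps each modality name (t1, t1ce, t2, flair) to a file and
    optionally 'label' to the segmentation.  All grids must agree.
    """
    missing = [m for m in MODALITIES if m not in paths]
    if missing:
        raise FileNotFoundError(f"missing modalities in case spec: {missing}")
    imgs = {}
    for mod in MODALITIES:
        p = Path(paths[mod])
        if not p.exists():
            raise FileNotFoundError(f"modality {mod!r}: no such file {p}")
        imgs[mod] = nib.load(str(p))
    shapes = {m: tuple(img.shape) for m, img in imgs.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"modality grid mismatch: {shapes}")
    affine = imgs[MODALITIES[0]].affine
    stack = np.stack([np.asarray(imgs[m].dataobj, dtype=np.float32) for m in MODALITIES])
    volume = MultimodalVolume(stack, affine=affine)
    label = None
    if "label" in paths and paths["label"]:
        limg = nib.load(str(paths["label"]))
        if tuple(limg.shape) != next(iter(shapes.values())):
            raise ValueError(f"label grid {tuple(limg.shape)} mismatches image grid "
                             f"({paths['label']})")
        label = LabelVolume(np.asarray(limg.dataobj).astype(np.int16), affine=affine)
    return volume, label


def save_labels(path, labels: np.ndarray, affine: np.ndarray | None = None):
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16),
                             np.eye(4) if affine is None else affine), str(path))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["case_id"] + [f"path_{m}" for m in MODALITIES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def manifest_row_paths(row) -> dict[str, str]:
    paths = {m: row[f"path_{m}"] for m in MODALITIES}
    if "path_label" in row and isinstance(row["path_label"], str):
        paths["label"] = row["path_label"]
    return paths


# -- preprocessing -----------------------------------------------------------

def normalize(v: MultimodalVolume) -> MultimodalVolume:
    """Per-modality z-score over nonzero (brain) voxels; background stays 0."""
    out = v.intensities.astype(np.float32).copy()
    for m in range(out.shape[0]):
        ch = out[m]
        mask = ch != 0
        if not mask.any():
            continue
        vals = ch[mask]
        ch[mask] = (vals - vals.mean()) / (vals.std() + NORM_EPS)
    return MultimodalVolume(out, affine=v.affine)


def pad_depth(v: MultimodalVolume, label: LabelVolume | None = None,
              source_depth: int = 155, target_depth: int = 160):
    """Zero-pad the depth axis 155 → 160 (2 slices before, 3 after)."""
    if v.shape[1] != source_depth:
        raise ValueError(f"expected depth {source_depth}, got {v.shape[1]}")
    before = (target_depth - source_depth) // 2
    after = target_depth - source_depth - before
    padded = MultimodalVolume(
        np.pad(v.intensities, ((0, 0), (before, after), (0, 0), (0, 0))), affine=v.affine)
    if label is None:
        return padded, None
    plabel = LabelVolume(np.pad(label.labels, ((before, after), (0, 0), (0, 0))),
                         affine=label.affine)
    return padded, plabel


def crop_depth(arr: np.ndarray, source_depth: int = 155, target_depth: int = 160) -> np.ndarray:
    """Undo :func:`pad_depth` on the depth axis (first spatial axis)."""
    before = (target_depth - source_depth) // 2
    sl = (slice(None),) * (arr.ndim - 3) + (slice(before, before + source_depth),)
    return arr[sl]


# -- patching ----------------------------------------------------------------

def _inplane_origins(extent: int, spec: PatchSpec) -> list[int]:
    """Sliding-window origins covering [0, extent) with window ``inplane``."""
    if extent < spec.inplane:
        raise ValueError(f"in-plane extent {extent} smaller than window {spec.inplane}")
    if extent == spec.inplane:
        return [0]
    origins = list(range(0, extent - spec.inplane, spec.stride))
    origins.append(extent - spec.inplane)
    return origins


def extract_patches(v: MultimodalVolume, label: LabelVolume | None,
                    spec: PatchSpec, rng: np.random.Generator | None = None) -> list[Patch]:
    """Split a padded volume into depth chunks × in-plane windows."""
    arr = v.intensities
    _, D, H, W = arr.shape
    if D % spec.depth_chunk:
        raise ValueError(f"depth {D} not divisible by chunk {spec.depth_chunk}")
    if H < spec.inplane or W < spec.inplane:
        raise ValueError(f"in-plane extent {(H, W)} smaller than window {spec.inplane}")
    rng = np.random.default_rng(0) if rng is None else rng
    lab = label.labels if label is not None else None
    patches: list[Patch] = []
    for z0 in range(0, D, spec.depth_chunk):
        z1 = z0 + spec.depth_chunk
        if spec.sampling == "grid":
            windows = [((H - spec.inplane) // 2, (W - spec.inplane) // 2)]
        elif spec.sampling == "sliding-window":
            windows = [(y, x) for y in _inplane_origins(H, spec)
                       for x in _inplane_origins(W, spec)]
        else:  # random-crop, optionally biased toward tumor-containing windows
            y0 = int(rng.integers(0, H - spec.inplane + 1))
            x0 = int(rng.integers(0, W - spec.inplane + 1))
            if (lab is not None and rng.random() < spec.tumor_bias):
                zs, ys, xs = np.nonzero(lab[z0:z1])
                if len(ys):
                    j = int(rng.integers(len(ys)))
                    y0 = int(np.clip(ys[j] - spec.inplane // 2, 0, H - spec.inplane))
                    x0 = int(np.clip(xs[j] - spec.inplane // 2, 0, W - spec.inplane))
            windows = [(y0, x0)]
        for y0, x0 in windows:
            img = arr[:, z0:z1, y0:y0 + spec.inplane, x0:x0 + spec.inplane]
            lpatch = (lab[z0:z1, y0:y0 + spec.inplane, x0:x0 + spec.inplane]
                      if lab is not None else None)
            patches.append(Patch(img, lpatch, (z0, y0, x0)))
    return patches


def random_flip(patch: Patch, rng: np.random.Generator,
                axes: tuple[int, ...] | None = None) -> tuple[Patch, tuple[int, ...]]:
    """Flip each spatial axis independently with probability 0.5.

    Image and label receive the identical flip.  Returns the flipped
    patch and the axis choices (so a flip can be undone or replayed).
    """
    if axes is None:
        axes = tuple(int(ax) for ax in range(3) if rng.random() < 0.5)
    img = patch.image
    lab = patch.label
    for ax in axes:
        img = np.flip(img, axis=ax + 1)
        if lab is not None:
            lab = np.flip(lab, axis=ax)
    return Patch(np.ascontiguousarray(img),
                 np.ascontiguousarray(lab) if lab is not None else None,
                 patch.offset), axes


def assemble_prediction(patch_preds: list[np.ndarray],
                        offsets: list[tuple[int, int, int]],
                        full_shape: tuple[int, int, int]) -> np.ndarray:
    """Scatter per-patch probability fields back onto the full grid.

    Overlapping contributions are averaged.  Raises if any voxel of the
    full grid is left uncovered.
    """
    n_ch = patch_preds[0].shape[0]
    acc = np.zeros((n_ch,) + tuple(full_shape), dtype=np.float64)
    cnt = np.zeros(full_shape, dtype=np.int32)
    for pred, (z0, y0, x0) in zip(patch_preds, offsets):
        _, dz, dy, dx = pred.shape
        acc[:, z0:z0 + dz, y0:y0 + dy, x0:x0 + dx] += pred
        cnt[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx] += 1
    if (cnt == 0).any():
        raise RuntimeError(f"prediction coverage gap: {(cnt == 0).sum()} voxels uncovered")
    return acc / cnt


def inference_patches(v: MultimodalVolume, spec: PatchSpec) -> list[Patch]:
    """Sliding-window cover of the whole grid for prediction."""
    cover = dataclasses.replace(spec, sampling="sliding-window")
    return extract_patches(v, None, cover)
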