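"""Synthetic multimodal brain phantoms with nested tumor compartments.

Each case is an ellipsoidal "brain" of nonzero intensity on a zero
background, containing three concentric ellipsoidal tumor compartments
(enhancing tumor inside necrotic core inside edema, so the evaluation
regions nest as ET ⊆ TC ⊆ WT by construction).  The four intensity
channels emulate the qualitative contrast of the standard MRI sequences
— FLAIR bright over edema, T1ce bright over enhancing tumor, T2 bright
over the whole lesion, T1 near-isointense — via an editable mean-
intensity table plus additive Gaussian noise.  The geometry is easy for
a small network to learn; no claim of MRI physics realism is made.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .losses_metrics import LBL_ED, LBL_ET, LBL_NCR

MODALITIES = ("t1", "t1ce", "t2", "flair")

#: mean intensity per (modality, tissue); tissues: brain, ed, ncr, et
DEFAULT_CONTRAST = {
    "t1":    {"brain": 1.0, "ed": 0.85, "ncr": 0.70, "et": 1.05},
    "t1ce":  {"brain": 1.0, "ed": 0.90, "ncr": 0.60, "et": 1.80},
    "t2":    {"brain": 1.0, "ed": 1.50, "ncr": 1.30, "et": 1.40},
    "flair": {"brain": 1.0, "ed": 1.80, "ncr": 1.20, "et": 1.30},
}


@dataclasses.dataclass
class PhantomConfig:
    grid: tuple[int, int, int] = (155, 240, 240)
    brain_axes: tuple[float, float, float] = (0.42, 0.40, 0.40)  # half-axes / grid
    ed_radius: float = 0.16    # compartment radii as fractions of min grid extent
    ncr_radius: float = 0.10
    et_radius: float = 0.06
    contrast: dict = dataclasses.field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 0.1
    seed: int = 41

    def __post_init__(self):
        if not (self.ed_radius > self.ncr_radius >= self.et_radius > 0):
            raise ValueError("compartment radii must satisfy ED > NCR >= ET > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @classmethod
    def tiny(cls, **kw) -> "PhantomConfig":
        """Small preset for desk-scale tests and training smoke runs."""
        kw.setdefault("grid", (32, 64, 64))
        kw.setdefault("ed_radius", 0.30)
        kw.setdefault("ncr_radius", 0.19)
        kw.setdefault("et_radius", 0.11)
        return cls(**kw)


def _ellipsoid(grid, center, half_axes) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(n) for n in grid], indexing="ij", sparse=True)
    r2 = sum(((c - mu) / ax) ** 2 for c, mu, ax in zip(coords, center, half_axes))
    return r2 <= 1.0


def generate_case(cfg: PhantomConfig,
                  rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One phantom: (4, Dz, Hy, Wx) intensities and integer label volume."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    grid = np.asarray(cfg.grid)
    brain_center = grid / 2.0
    brain_half = grid * np.asarray(cfg.brain_axes)
    min_extent = float(grid.min())
    radii = {"ed": cfg.ed_radius * min_extent,
             "ncr": cfg.ncr_radius * min_extent,
             "et": cfg.et_radius * min_extent}
    margin = brain_half - radii["ed"]
    if np.any(margin <= 0):
        raise ValueError("edema compartment does not fit inside the brain ellipsoid")
    # tumor center uniform in the box where the whole lesion stays in-brain
    offset = rng.uniform(-0.5, 0.5, size=3) * margin
    center = brain_center + offset

    brain = _ellipsoid(cfg.grid, brain_center, brain_half)
    ed_m = _ellipsoid(cfg.grid, center, [radii["ed"]] * 3) & brain
    ncr_m = _ellipsoid(cfg.grid, center, [radii["ncr"]] * 3) & brain
    et_m = _ellipsoid(cfg.grid, center, [radii["et"]] * 3) & brain

    labels = np.zeros(cfg.grid, dtype=np.int16)
    labels[ed_m] = LBL_ED
    labels[ncr_m & ~et_m] = LBL_NCR
    labels[et_m] = LBL_ET

    tissue_masks = {"brain": brain & (labels == 0), "ed": labels == LBL_ED,
                    "ncr": labels == LBL_NCR, "et": labels == LBL_ET}
    volume = np.zeros((len(MODALITIES),) + tuple(cfg.grid), dtype=np.float32)
    for i, mod in enumerate(MODALITIES):
        ch = np.zeros(cfg.grid, dtype=np.float32)
        for tissue, mask in tissue_masks.items():
            ch[mask] = cfg.contrast[mod][tissue]
        if cfg.noise_sd > 0:
            ch[brain] += rng.normal(0.0, cfg.noise_sd, size=int(brain.sum())).astype(np.float32)
        volume[i] = ch
    return volume, labels


def generate_cohort(n: int, cfg: PhantomConfig, seed: int, out_dir) -> Path:
    """Write ``n`` phantom cases as NIfTI files plus a manifest.

    Returns the manifest path.  Case sub-seeds are spawned from ``seed``
    so cohorts are reproducible and cases mutually distinct.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    rows = []
    children = np.random.SeedSequence(seed).spawn(n)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        volume, labels = generate_case(cfg, rng)
        case_id = f"case_{i:03d}"
        row = {"case_id": case_id}
        for m, mod in enumerate(MODALITIES):
            path = out_dir / f"{case_id}_{mod}.nii.gz"
            nib.save(nib.Nifti1Image(volume[m], affine), path)
            row[f"path_{mod}"] = str(path)
        label_path = out_dir / f"{case_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(labels, affine), label_path)
        row["path_label"] = str(label_path)
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
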