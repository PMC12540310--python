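"""MAUNet: a 3D encoder–decoder segmentation network with attention.

Architecture (channel widths shown for the default ``base_width=32``):

* stem: 5×5×5 conv, 4 modalities → 32 maps
* encoder: three SMDConv stages (32, 64, 128), each followed by 2×
  max-pool downsampling; an SMDConv stage is two 3×3×3 conv blocks plus
  an SMWA attention block
* bottleneck (256 maps): dilated conv (rate 2) → CFC → dilated conv
  (rate 4) → CFC
* decoder: three stages of trilinear 2× upsampling, gated skip fusion
  with the matching encoder stage, and an SMDConv stage (128, 64, 32)
* head: 1×1×1 conv to three sigmoid channels, one per nested tumor
  region (whole tumor, tumor core, enhancing tumor)

The three attention families (skip gates, SMWA, CFC) can be switched off
independently, yielding the ablation family from the plain baseline
(double-conv U-Net) to the full model; a disabled family contributes no
parameters.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from . import nn
from .cfc import CFC, DEFAULT_PYRAMID_BINS
from .gated_skip import GatedSkip
from .nn import tensor as T
from .nn.tensor import Tensor
from .smwa import SMWA

REGION_NAMES = ("wt", "tc", "et")

CHECKPOINT_VERSION = 1


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters, including ablation toggles."""

    base_width: int = 32
    in_modalities: int = 4
    out_regions: int = 3
    stem_kernel: int = 5
    dilation_rates: tuple[int, int] = (2, 4)
    enable_gate: bool = True
    enable_smwa: bool = True
    enable_cfc: bool = True
    reduction: int = 4            # MLP bottleneck ratio for SMWA + gates
    smwa_kernel: int = 3
    pyramid_bins: tuple[int, ...] = DEFAULT_PYRAMID_BINS
    cfc_cosine: bool = True
    dtype: str = "float64"

    def __post_init__(self):
        if self.base_width % self.reduction:
            raise ValueError(
                f"base_width {self.base_width} must be divisible by reduction {self.reduction}")
        self.dilation_rates = tuple(self.dilation_rates)
        self.pyramid_bins = tuple(self.pyramid_bins)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class SMDConv(nn.Module):
    """Two conv blocks plus optional SMWA attention; shape preserving."""

    def __init__(self, in_ch: int, out_ch: int, cfg: NetworkConfig, rng):
        dt = cfg.np_dtype
        self.conv1 = nn.ConvBlock(in_ch, out_ch, 3, rng, dtype=dt)
        self.conv2 = nn.ConvBlock(out_ch, out_ch, 3, rng, dtype=dt)
        self.attn = (SMWA(out_ch, rng, cfg.reduction, cfg.smwa_kernel, dtype=dt)
                     if cfg.enable_smwa else None)

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv2(self.conv1(x))
        return self.attn(x) if self.attn is not None else x


def smdconv_block(f, width: int, cfg: NetworkConfig, rng=None) -> Tensor:
    """Build a fresh SMDConv stage for ``width`` channels and apply it."""
    rng = np.random.default_rng(0) if rng is None else rng
    f = nn.as_tensor(f)
    return SMDConv(f.shape[0], width, cfg, rng)(f)


class MAUNet(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng(0) if rng is None else rng
        dt = cfg.np_dtype
        bw = cfg.base_width
        self.cfg = cfg
        self.stem = nn.ConvBlock(cfg.in_modalities, bw, cfg.stem_kernel, rng, dtype=dt)
        enc_widths = (bw, 2 * bw, 4 * bw)
        self.encoders = [SMDConv(w_in, w_out, cfg, rng)
                         for w_in, w_out in zip((bw,) + enc_widths[:-1], enc_widths)]
        bott = 8 * bw
        d1, d2 = cfg.dilation_rates
        self.bott_conv1 = nn.ConvBlock(4 * bw, bott, 3, rng, dilation=d1, dtype=dt)
        self.bott_conv2 = nn.ConvBlock(bott, bott, 3, rng, dilation=d2, dtype=dt)
        if cfg.enable_cfc:
            self.cfc1 = CFC(bott, rng, pyramid_bins=cfg.pyramid_bins,
                            cosine=cfg.cfc_cosine, dtype=dt)
            self.cfc2 = CFC(bott, rng, pyramid_bins=cfg.pyramid_bins,
                            cosine=cfg.cfc_cosine, dtype=dt)
        else:
            self.cfc1 = self.cfc2 = None
        dec_in = (bott, 4 * bw, 2 * bw)        # decoder input widths before fusion
        skip_w = (4 * bw, 2 * bw, bw)
        dec_out = (4 * bw, 2 * bw, bw)
        self.gates = ([GatedSkip(s, u, rng, cfg.reduction, dtype=dt)
                       for s, u in zip(skip_w, dec_in)] if cfg.enable_gate else None)
        self.decoders = [SMDConv(s + u, o, cfg, rng)
                         for s, u, o in zip(skip_w, dec_in, dec_out)]
        self.head = nn.Conv3d(bw, cfg.out_regions, 1, rng, dtype=dt)

    def forward(self, volume) -> Tensor:
        x = nn.as_tensor(volume)
        if x.ndim != 4 or x.shape[0] != self.cfg.in_modalities:
            raise ValueError(
                f"expected ({self.cfg.in_modalities}, D, H, W) input, got {x.shape}")
        if any(s % 8 for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by 8 (three 2x downsamplings)")
        if x.data.dtype != self.cfg.np_dtype:
            x = Tensor(x.data.astype(self.cfg.np_dtype), requires_grad=x.requires_grad)
        x = self.stem(x)
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = T.maxpool2(x)
        x = self.bott_conv1(x)
        if self.cfc1 is not None:
            x = self.cfc1(x)
        x = self.bott_conv2(x)
        if self.cfc2 is not None:
            x = self.cfc2(x)
        for i, dec in enumerate(self.decoders):
            skip = skips[-1 - i]
            x = T.upsample2_trilinear(x)
            if self.gates is not None:
                x = self.gates[i](skip, x)
            else:
                x = T.concat([skip, x], axis=0)
            x = dec(x)
        return T.sigmoid(self.head(x))

    def predict(self, volume) -> np.ndarray:
        """Inference pass without graph construction; returns an ndarray."""
        with nn.no_grad():
            return self.forward(volume).data


def build_maunet(cfg: NetworkConfig, seed: int = 0) -> MAUNet:
    """Construct a MAUNet with parameters drawn from ``seed``."""
    return MAUNet(cfg, np.random.default_rng(seed))


# -- checkpoint I/O ----------------------------------------------------------

def save_checkpoint(path, net: MAUNet, extra: Optional[dict] = None):
    """Serialize parameters plus embedded config to a single .npz archive."""
    meta = {"version": CHECKPOINT_VERSION, "config": net.cfg.to_dict(),
            "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in net.state_dict().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[MAUNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = NetworkConfig.from_dict(meta["config"])
        net = build_maunet(cfg)
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    net.load_state_dict(state)
    return net, meta.get("extra", {})
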