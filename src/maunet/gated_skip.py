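"""Channel-gated fusion of encoder skip features with decoder features.

The encoder skip tensor and the upsampled decoder tensor (same spatial
shape, possibly different channel counts) are concatenated along the
channel axis.  A global-average-pooled channel descriptor passes through
a two-layer MLP and a sigmoid, producing one retention weight in (0, 1)
per channel, which is broadcast-multiplied onto the concatenated stack:
features are softly down-weighted, never hard-discarded.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor


class GatedSkip(nn.Module):
    def __init__(self, skip_ch: int, up_ch: int, rng, reduction: int = 4,
                 dtype=np.float64):
        self.mlp = nn.ChannelMLP(skip_ch + up_ch, reduction, rng, dtype=dtype)
        self.skip_ch = skip_ch
        self.up_ch = up_ch

    def gates(self, cat: Tensor) -> Tensor:
        return T.sigmoid(self.mlp(cat.mean(axis=(1, 2, 3))))

    def forward(self, skip: Tensor, up: Tensor) -> Tensor:
        skip, up = nn.as_tensor(skip), nn.as_tensor(up)
        if skip.shape[1:] != up.shape[1:]:
            raise ValueError(
                f"spatial mismatch: skip {skip.shape[1:]} vs decoder {up.shape[1:]}; "
                "upsample before gating")
        cat = T.concat([skip, up], axis=0)
        g = self.gates(cat)
        return T.reshape(g, (-1, 1, 1, 1)) * cat


def gate_fuse(skip, up, params: GatedSkip) -> Tensor:
    """Functional wrapper; accepts ndarrays or tensors."""
    return params(nn.as_tensor(skip), nn.as_tensor(up))
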