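"""Spatial multi-dimensional weighted attention (SMWA).

The block reweights a feature field f ∈ R^{C×D×H×W} in two stages:

1. **Channel attention** — global average- and max-pooled channel
   descriptors pass through one shared two-layer MLP; the sigmoid of the
   summed outputs gives a weight per channel, broadcast-multiplied onto f.
2. **Per-axis slice attention** — for each spatial axis (depth, height,
   width) the channel-attended field is compressed to an average and a
   maximum descriptor per slice along that axis; a 1-D convolution with
   footprint (1, 1, k) over the two stacked descriptors yields one logit
   per slice, a sigmoid turns it into a slice weight, and the weighted
   field is scaled by a learnable scalar per branch.

The block output is the sum of the three axis-branch outputs.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

AXES = {"D": 1, "H": 2, "W": 3}


class ChannelAttention(nn.Module):
    """Shared-MLP channel attention over global avg/max descriptors."""

    def __init__(self, channels: int, rng, reduction: int = 4, dtype=np.float64):
        if reduction < 1:
            raise ValueError(f"reduction must be >= 1, got {reduction}")
        # hidden width clamps to >= 1 so narrow stems remain valid
        self.mlp = nn.ChannelMLP(channels, reduction, rng, dtype=dtype)
        self.channels = channels

    def weights(self, f: Tensor) -> Tensor:
        f = nn.as_tensor(f)
        if f.shape[0] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {f.shape[0]}")
        avg = f.mean(axis=(1, 2, 3))
        mx = f.max(axis=(1, 2, 3))
        return T.sigmoid(self.mlp(avg) + self.mlp(mx))

    def forward(self, f: Tensor) -> Tensor:
        w = self.weights(f)
        return T.reshape(w, (-1, 1, 1, 1)) * f


class AxisAttention(nn.Module):
    """Slice attention along one spatial axis.

    ``kernel`` taps mix the (avg, max) descriptor pair of ``kernel``
    neighbouring slices into one logit per slice; symmetric zero padding
    keeps the logit sequence as long as the axis.
    """

    def __init__(self, axis: str, rng, kernel: int = 3, dtype=np.float64):
        if axis not in AXES:
            raise ValueError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and positive, got {kernel}")
        fan_in = 2 * kernel
        self.kernel_weight = nn.Parameter(
            (rng.standard_normal((kernel, 2)) * np.sqrt(1.0 / fan_in)).astype(dtype))
        self.branch_scale = nn.Parameter(np.asarray(1.0, dtype=dtype))
        self.axis = axis
        self.kernel = kernel

    def slice_weights(self, f_c: Tensor) -> Tensor:
        f_c = nn.as_tensor(f_c)
        ax = AXES[self.axis]
        other = tuple(i for i in range(4) if i != ax)
        avg = f_c.mean(axis=other)          # (A,)
        mx = f_c.max(axis=other)            # (A,)
        desc = T.concat([T.reshape(avg, (1, -1)), T.reshape(mx, (1, -1))], axis=0)  # (2, A)
        A = desc.shape[1]
        k = self.kernel
        pad = (k - 1) // 2
        # replicate (edge) padding keeps the logit sequence as long as the
        # axis and preserves the symmetry of axis-constant fields
        pieces = [desc[:, :1]] * pad + [desc] + [desc[:, A - 1:]] * pad
        padded = T.concat(pieces, axis=1) if pad else desc  # (2, A + 2*pad)
        logits = None
        for x in range(k):
            tap = T.matmul(T.reshape(self.kernel_weight[x], (1, 2)), padded[:, x:x + A])
            logits = tap if logits is None else logits + tap
        return T.sigmoid(T.reshape(logits, (A,)))

    def forward(self, f_c: Tensor) -> Tensor:
        ax = AXES[self.axis]
        w = self.slice_weights(f_c)
        shape = [1, 1, 1, 1]
        shape[ax] = -1
        return self.branch_scale * (T.reshape(w, shape) * f_c)


class SMWA(nn.Module):
    """Channel attention followed by three fused per-axis branches."""

    def __init__(self, channels: int, rng, reduction: int = 4, kernel: int = 3,
                 dtype=np.float64):
        self.channel = ChannelAttention(channels, rng, reduction, dtype=dtype)
        self.axis_d = AxisAttention("D", rng, kernel, dtype=dtype)
        self.axis_h = AxisAttention("H", rng, kernel, dtype=dtype)
        self.axis_w = AxisAttention("W", rng, kernel, dtype=dtype)

    def forward(self, f: Tensor) -> Tensor:
        f_c = self.channel(f)
        return self.axis_d(f_c) + self.axis_h(f_c) + self.axis_w(f_c)


# -- functional surface ------------------------------------------------------

def channel_attention(f, params: ChannelAttention) -> Tensor:
    """Apply channel attention; ``f`` may be an ndarray or Tensor."""
    return params(nn.as_tensor(f))


def axis_attention(f_c, axis: str, params: AxisAttention) -> Tensor:
    if params.axis != axis:
        raise ValueError(f"params built for axis {params.axis!r}, requested {axis!r}")
    return params(nn.as_tensor(f_c))


def smwa_forward(f, params: SMWA) -> Tensor:
    return params(nn.as_tensor(f))
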