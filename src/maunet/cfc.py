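"""Contextual feature calibration (CFC).

Given a feature field X ∈ R^{C×D×H×W}, the block

1. projects X to a reduced query field Q ∈ R^{C'×D×H×W} (1×1×1 conv);
2. runs **cascaded pyramid pooling**: adaptive max pooling to a sequence
   of grids, each stage pooling the previous stage's output; all pooled
   cells are flattened into a context matrix Z ∈ R^{C'×M};
3. projects Z to keys K ∈ R^{C'×M} and values V ∈ R^{C×M};
4. computes a row-stochastic affinity A ∈ R^{N×M} (N = D·H·W) by a
   softmax over cosine similarities between each pixel vector of Q and
   each key;
5. aggregates per-pixel context E = V·Aᵀ, reshaped to (C, D, H, W);
6. recalibrates: E' = tanh(W2(W1(X + E))) ⊙ E + E, where W1 is a 1×1×1
   and W2 a shape-preserving 3×3×3 convolution;
7. returns the residual sum Y = X + E'.

Because the gate tanh(·) lies in (−1, 1), the recalibration factor
(1 + gate) lies in (0, 2): the block can damp or amplify the aggregated
context but never flips its sign.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

#: cascade order: largest grid first, each stage pools the previous one
DEFAULT_PYRAMID_BINS = (5, 3, 1)


class CFC(nn.Module):
    def __init__(self, channels: int, rng, reduced: int | None = None,
                 pyramid_bins=DEFAULT_PYRAMID_BINS, cosine: bool = True,
                 cascade: bool = True, dtype=np.float64):
        reduced = channels // 2 if reduced is None else reduced
        if reduced >= channels or reduced < 1:
            raise ValueError(f"reduced channel count must be in [1, {channels}), got {reduced}")
        if not pyramid_bins:
            raise ValueError("pyramid_bins must be nonempty")
        self.reduce_conv = nn.Conv3d(channels, reduced, 1, rng, dtype=dtype)
        self.key_proj = nn.Linear(reduced, reduced, rng, dtype=dtype)
        self.value_proj = nn.Linear(reduced, channels, rng, dtype=dtype)
        self.crb_w1 = nn.Conv3d(channels, channels, 1, rng, dtype=dtype)
        self.crb_w2 = nn.Conv3d(channels, channels, 3, rng, dtype=dtype)
        self.pyramid_bins = tuple(pyramid_bins)
        self.cosine = cosine
        self.cascade = cascade
        self.channels = channels
        self.reduced = reduced

    def forward(self, x: Tensor) -> Tensor:
        return cfc_forward(x, self)


# -- stage functions ---------------------------------------------------------

def reduce_query(x, p: CFC) -> Tensor:
    """Project the input field to the reduced query channel width."""
    x = nn.as_tensor(x)
    if x.shape[0] != p.channels:
        raise ValueError(f"expected {p.channels} channels, got {x.shape[0]}")
    return p.reduce_conv(x)


def cascaded_pyramid_pool(q, p: CFC) -> Tensor:
    """Pool the query field to the pyramid grids and stack all cells.

    Returns Z with shape (C', M), M = Σ bins_i³ (bins clamp to the
    available extent on small inputs).
    """
    q = nn.as_tensor(q)
    stages = []
    current = q
    for b in p.pyramid_bins:
        if b < 1:
            raise ValueError(f"pyramid bin must be positive, got {b}")
        source = current if p.cascade else q
        # bins clamp per-axis to the available extent on small inputs
        pooled = T.adaptive_maxpool3d(source, (b, b, b))
        stages.append(T.reshape(pooled, (q.shape[0], -1)))
        current = pooled
    return T.concat(stages, axis=1)


def _l2_normalize_rows(m: Tensor, eps: float = 1e-8) -> Tensor:
    # eps inside the sqrt keeps the gradient finite for zero-norm vectors
    norm = T.sqrt(T.tsum(m * m, axis=1, keepdims=True) + eps * eps)
    return m * T.reciprocal(norm)


def context_affinity(q, k, cosine: bool = True) -> Tensor:
    """Row-stochastic pixel-to-context affinity.

    ``q`` is the query field (C', D, H, W) or an already-flattened (N, C')
    matrix; ``k`` the key matrix (C', M).  Similarity defaults to the
    cosine of the two vectors (zero-norm vectors clamp to similarity 0),
    followed by a softmax over contexts.
    """
    q = nn.as_tensor(q)
    k = nn.as_tensor(k)
    q_flat = T.reshape(q, (q.shape[0], -1)).T if q.ndim == 4 else q
    if q_flat.shape[1] != k.shape[0]:
        raise ValueError(f"query width {q_flat.shape[1]} != key height {k.shape[0]}")
    if cosine:
        q_flat = _l2_normalize_rows(q_flat)
        k = _l2_normalize_rows(k.T).T
    return T.softmax(T.matmul(q_flat, k), axis=1)


def aggregate_context(v, a, spatial: tuple[int, int, int]) -> Tensor:
    """E = V · Aᵀ reshaped to (C, D, H, W).

    Each pixel's context vector is a convex combination of V's columns.
    """
    v, a = nn.as_tensor(v), nn.as_tensor(a)
    if v.shape[1] != a.shape[1]:
        raise ValueError(f"value count {v.shape[1]} != affinity contexts {a.shape[1]}")
    e = T.matmul(v, a.T)
    return T.reshape(e, (v.shape[0],) + tuple(spatial))


def recalibrate_context(x, e, p: CFC) -> Tensor:
    """E' = tanh(W2(W1(X + E))) ⊙ E + E."""
    x, e = nn.as_tensor(x), nn.as_tensor(e)
    if x.shape != e.shape:
        raise ValueError(f"shape mismatch: X {x.shape} vs E {e.shape}")
    gate = T.tanh(p.crb_w2(p.crb_w1(x + e)))
    return gate * e + e


def cfc_forward(x, p: CFC) -> Tensor:
    """Full calibration pass, Y = X + E'."""
    x = nn.as_tensor(x)
    q = reduce_query(x, p)
    z = cascaded_pyramid_pool(q, p)
    k = p.key_proj(z.T).T
    v = p.value_proj(z.T).T
    a = context_affinity(q, k, cosine=p.cosine)
    e = aggregate_context(v, a, x.shape[1:])
    e_prime = recalibrate_context(x, e, p)
    return x + e_prime
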