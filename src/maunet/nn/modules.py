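"""Layer abstractions over the autodiff tensors.

Layout convention is channel-first without a batch axis — (C, D, H, W) —
matching the single-volume batches used for training (batch size 1).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal module container with recursive parameter discovery."""

    def __setattr__(self, name, value):
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = T.matmul(x, self.weight.T) if x.ndim > 1 else T.matmul(self.weight, x)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, dilation: int = 1, bias: bool = True,
                 dtype=np.float64):
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias, padding=self.padding, dilation=self.dilation)


class InstanceNorm3d(Module):
    """Per-channel normalization over the spatial axes with affine rescale.

    With single-volume batches this is the only normalization whose
    statistics are well defined, so it is used after every convolution.
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(1, 2, 3), keepdims=True)
        inv = T.reciprocal(T.sqrt(var + self.eps))
        g = T.reshape(self.gamma, (-1, 1, 1, 1))
        b = T.reshape(self.beta, (-1, 1, 1, 1))
        return centered * inv * g + b


class ConvBlock(Module):
    """Conv3d -> InstanceNorm -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dilation: int = 1,
                 dtype=np.float64):
        self.conv = Conv3d(in_ch, out_ch, kernel, rng, dilation=dilation, dtype=dtype)
        self.norm = InstanceNorm3d(out_ch, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.norm(self.conv(x)))


class ChannelMLP(Module):
    """Two affine maps over a channel descriptor with a rectifier between.

    Used for channel attention and skip gating; the bottleneck width is
    ``channels // reduction``.
    """

    def __init__(self, channels: int, reduction: int, rng, dtype=np.float64):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(T.relu(self.fc1(x)))
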