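"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation builds a node
holding references to its parent tensors and a closure that maps the
output gradient to per-parent gradients.  ``Tensor.backward`` walks the
graph in reverse topological order and accumulates gradients into
``.grad`` (plain ndarrays).  Only the operations the segmentation
network needs are implemented; all of them support arbitrary dtypes and
keep the dtype of their inputs.
"""

from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not (parent.requires_grad or parent._parents):
                    continue
                g = np.asarray(g, dtype=parent.data.dtype)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return mul(self, reciprocal(as_tensor(other)))

    def __rtruediv__(self, other):
        return mul(reciprocal(self), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take_slice(self, idx)

    # -- shorthand methods ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    @property
    def T(self):
        return transpose(self, None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    """Build an output tensor, attaching the tape node when grad is enabled."""
    out = Tensor(data)
    parents = tuple(parents)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# -- elementwise -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape),
                            _unbroadcast(g * a.data, b.shape)))


def reciprocal(a: Tensor) -> Tensor:
    a = as_tensor(a)
    inv = 1.0 / a.data
    return _node(inv, (a,), lambda g: (-g * inv * inv,))


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p
    return _node(out, (a,), lambda g: (g * p * a.data ** (p - 1),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _node(out, (a,), lambda g: (g * 0.5 / out,))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _node(out, (a,), lambda g: (g * (1.0 - out * out),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    out = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                   np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _node(np.where(mask, a.data, 0.0), (a,), lambda g: (g * mask,))


def clamp(a, lo: float, hi: float) -> Tensor:
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)
    return _node(out, (a,), lambda g: (g * inside,))


# -- reductions --------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            g = np.expand_dims(g, tuple(ax % a.ndim for ax in axes))
        return (np.broadcast_to(g, a.shape).copy(),)

    return _node(out, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(a, axis=None, keepdims=False) -> Tensor:
    """Max reduction; gradient is split evenly among tied argmax positions."""
    a = as_tensor(a)
    out = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            full = out
            gg = g
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(ax % a.ndim for ax in axes)
            full = out if keepdims else np.expand_dims(out, axes)
            gg = g if keepdims else np.expand_dims(g, axes)
        mask = (a.data == full)
        count = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        if axis is not None and not keepdims:
            pass  # count already keepdims via sum keepdims=True
        return (mask * (gg / count),)

    return _node(out, (a,), backward)


# -- shape manipulation ------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    return _node(out, tuple(tensors),
                 lambda g: tuple(np.split(g, splits, axis=axis)))


def take_slice(a, idx) -> Tensor:
    a = as_tensor(a)
    out = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return (full,)

    return _node(out, (a,), backward)


def pad_zero(a, pads) -> Tensor:
    """Zero-pad; ``pads`` is a per-axis list of (before, after)."""
    a = as_tensor(a)
    out = np.pad(a.data, pads)
    sl = tuple(slice(b, b + s) for (b, _), s in zip(pads, a.shape))
    return _node(out, (a,), lambda g: (g[sl],))


# -- linear algebra ----------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.ndim == 2 and b.ndim == 2:
            return g @ b.data.T, a.data.T @ g
        if a.ndim == 2 and b.ndim == 1:      # (m,k)@(k,) -> (m,)
            return np.outer(g, b.data), a.data.T @ g
        if a.ndim == 1 and b.ndim == 2:      # (k,)@(k,n) -> (n,)
            return b.data @ g, np.outer(a.data, g)
        return g * b.data, g * a.data        # 1-D dot

    return _node(a.data @ b.data, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return e / tsum(e, axis=axis, keepdims=True)


# -- spatial primitives (channel-first (C, D, H, W) layout, no batch axis) ---

def conv3d(x, w, b=None, padding: int = 0, dilation: int = 1) -> Tensor:
    """3D cross-correlation, stride 1.

    x: (Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    Symmetric zero padding; implemented as a shift-and-accumulate over the
    kernel taps so memory stays at one padded copy of the input.
    """
    x, w = as_tensor(x), as_tensor(w)
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    if x.shape[0] != cin:
        raise ValueError(f"conv3d: input has {x.shape[0]} channels, kernel expects {cin}")
    p, dl = padding, dilation
    D, H, W = x.shape[1:]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    oD = D + 2 * p - dl * (k - 1)
    oH = H + 2 * p - dl * (k - 1)
    oW = W + 2 * p - dl * (k - 1)
    if min(oD, oH, oW) < 1:
        raise ValueError("conv3d: kernel footprint exceeds padded input extent")
    wm = w.data.reshape(cout, cin, -1)
    out = np.zeros((cout, oD, oH, oW), dtype=x.dtype)
    taps = [(kz, ky, kx) for kz in range(k) for ky in range(k) for kx in range(k)]
    for t, (kz, ky, kx) in enumerate(taps):
        xs = xp[:, kz * dl:kz * dl + oD, ky * dl:ky * dl + oH, kx * dl:kx * dl + oW]
        out += np.tensordot(wm[:, :, t], xs, axes=1)
    if b is not None:
        b = as_tensor(b)
        out += b.data[:, None, None, None]

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for t, (kz, ky, kx) in enumerate(taps):
            xs = xp[:, kz * dl:kz * dl + oD, ky * dl:ky * dl + oH, kx * dl:kx * dl + oW]
            dw[:, :, kz, ky, kx] = np.tensordot(g, xs, axes=([1, 2, 3], [1, 2, 3]))
            dxp[:, kz * dl:kz * dl + oD, ky * dl:ky * dl + oH, kx * dl:kx * dl + oW] += \
                np.tensordot(wm[:, :, t].T, g, axes=1)
        dx = dxp[:, p:p + D, p:p + H, p:p + W] if p else dxp
        if b is None:
            return dx, dw
        return dx, dw, g.sum(axis=(1, 2, 3))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2(x) -> Tensor:
    """2x2x2 max pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2: spatial dims {(D, H, W)} must be even")
    xv = x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = xv.max(axis=(2, 4, 6))

    def backward(g):
        full = out[:, :, None, :, None, :, None]
        mask = (xv == full)
        count = mask.sum(axis=(2, 4, 6), keepdims=True)
        gx = mask * (g[:, :, None, :, None, :, None] / count)
        return (gx.reshape(x.shape),)

    return _node(out, (x,), backward)


def adaptive_maxpool3d(x, bins) -> Tensor:
    """Adaptive max pooling of a (C, D, H, W) field to an output grid.

    ``bins`` is (bz, by, bx); window boundaries follow the usual
    floor/ceil adaptive-pooling convention so the windows tile the input.
    """
    x = as_tensor(x)
    C = x.shape[0]
    spatial = x.shape[1:]
    bins = tuple(int(min(b, s)) for b, s in zip(bins, spatial))
    bz, by, bx = bins

    def bounds(n_out, n_in):
        return [(int(np.floor(i * n_in / n_out)), int(np.ceil((i + 1) * n_in / n_out)))
                for i in range(n_out)]

    zb, yb, xb = bounds(bz, spatial[0]), bounds(by, spatial[1]), bounds(bx, spatial[2])
    out = np.empty((C, bz, by, bx), dtype=x.dtype)
    argmax = np.empty((C, bz, by, bx), dtype=np.intp)
    flat = x.data.reshape(C, -1)
    HW = spatial[1] * spatial[2]
    for iz, (z0, z1) in enumerate(zb):
        for iy, (y0, y1) in enumerate(yb):
            for ix, (x0, x1) in enumerate(xb):
                win = x.data[:, z0:z1, y0:y1, x0:x1].reshape(C, -1)
                loc = win.argmax(axis=1)
                out[:, iz, iy, ix] = win[np.arange(C), loc]
                dz, dy, dx = z1 - z0, y1 - y0, x1 - x0
                lz, rem = np.divmod(loc, dy * dx)
                ly, lx = np.divmod(rem, dx)
                argmax[:, iz, iy, ix] = (z0 + lz) * HW + (y0 + ly) * spatial[2] + (x0 + lx)

    def backward(g):
        gx = np.zeros_like(flat)
        cols = argmax.reshape(C, -1)
        np.add.at(gx, (np.arange(C)[:, None], cols), g.reshape(C, -1))
        return (gx.reshape(x.shape),)

    return _node(out, (x,), backward)


def _upsample_matrix(n: int, dtype) -> np.ndarray:
    """Linear-interpolation matrix for 2x upsampling (half-pixel centers)."""
    P = np.zeros((2 * n, n), dtype=dtype)
    for j in range(2 * n):
        s = (j + 0.5) / 2.0 - 0.5
        s = min(max(s, 0.0), n - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n - 1)
        w1 = s - i0
        P[j, i0] += 1.0 - w1
        P[j, i1] += w1
    return P


def upsample2_trilinear(x) -> Tensor:
    """Trilinear 2x upsampling of a (C, D, H, W) field."""
    x = as_tensor(x)
    C, D, H, W = x.shape
    Pd = _upsample_matrix(D, x.data.dtype)
    Ph = _upsample_matrix(H, x.data.dtype)
    Pw = _upsample_matrix(W, x.data.dtype)

    def apply(arr, Pz, Py, Px):
        arr = np.einsum("od,cdhw->cohw", Pz, arr)
        arr = np.einsum("oh,cdhw->cdow", Py, arr)
        return np.einsum("ow,cdhw->cdho", Px, arr)

    out = apply(x.data, Pd, Ph, Pw)
    return _node(out, (x,), lambda g: (apply(g, Pd.T, Ph.T, Pw.T),))
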