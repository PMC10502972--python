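"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation networks need: 2-D
convolution (arbitrary kernel/stride, zero or replicate padding), 2x2 max
pooling, nearest-neighbour 2x upsampling, batch normalization, ReLU,
sigmoid, channel concatenation, axis means, elementwise arithmetic and
full reductions.  Gradients are accumulated by topological traversal of
the recorded graph; every op's backward is verified against numeric
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor"]


class Tensor:
    """An array plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ #
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the closure so the graph can be collected
            node._backward = None
            node._parents = ()

    # ------------------------------------------------------------------ #
    # arithmetic (sufficient for losses; not a full numpy emulation)

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def sum(self):
        return sum_all(self)

    def mean(self):
        return sum_all(self) * (1.0 / self.data.size)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------- #
# elementwise / reduction ops


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

    return _make(a.data / b.data, (a, b), backward)


def sum_all(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, float(g)))

    return _make(a.data.sum(), (a,), backward)


def relu(a: Tensor) -> Tensor:
    pos = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * pos)

    return _make(np.where(pos, a.data, 0.0), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def mean_axis(a: Tensor, axis: int) -> Tensor:
    """Mean along one axis, keepdims=True (strip pooling)."""
    n = a.data.shape[axis]
    out_data = a.data.mean(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate (N, C, H, W) tensors along the channel axis."""
    ca = a.data.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _make(np.concatenate([a.data, b.data], axis=1), (a, b), backward)


# ---------------------------------------------------------------------- #
# spatial ops on (N, C, H, W)


def _pad_input(x: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    np_mode = "constant" if mode == "zeros" else "edge"
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode=np_mode)


def _unpad_grad(gp: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    """Fold the gradient of a padded array back onto the original array."""
    if ph == 0 and pw == 0:
        return gp
    if mode == "zeros":
        return gp[:, :, ph : gp.shape[2] - ph, pw : gp.shape[3] - pw]
    # replicate padding: padded border rows/cols map onto the edge cells
    g = gp.copy()
    if ph > 0:
        g[:, :, ph, :] += g[:, :, :ph, :].sum(axis=2)
        g[:, :, -ph - 1, :] += g[:, :, -ph:, :].sum(axis=2)
        g = g[:, :, ph : g.shape[2] - ph, :]
    if pw > 0:
        g[:, :, :, pw] += g[:, :, :, :pw].sum(axis=3)
        g[:, :, :, -pw - 1] += g[:, :, :, -pw:].sum(axis=3)
        g = g[:, :, :, pw : g.shape[3] - pw]
    return g


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor,
    stride: tuple[int, int] = (1, 1),
    padding: tuple[int, int] = (0, 0),
    pad_mode: str = "zeros",
) -> Tensor:
    """Cross-correlation of (N,Cin,H,W) with (Cout,Cin,kh,kw) weights."""
    N, Cin, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    sh, sw = stride
    ph, pw = padding
    xp = _pad_input(x.data, ph, pw, pad_mode)
    Ho = (xp.shape[2] - kh) // sh + 1
    Wo = (xp.shape[3] - kw) // sw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    # (N, Cin, Ho, Wo, kh, kw) -> (N*Ho*Wo, Cin*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out = cols @ wmat.T + b.data
    out = out.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ wmat).reshape(N, Ho, Wo, Cin, kh, kw)
            gcols = gcols.transpose(0, 3, 4, 5, 1, 2)  # N,Cin,kh,kw,Ho,Wo
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += (
                        gcols[:, :, i, j]
                    )
            x._accumulate(_unpad_grad(gxp, ph, pw, pad_mode))

    return _make(out, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            ).reshape(N, C, H, W)
            x._accumulate(gx)

    return _make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour doubling of both spatial dimensions."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            N, C, H2, W2 = g.shape
            x._accumulate(
                g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            )

    return _make(out, (x,), backward)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.
    """
    C = x.data.shape[1]
    gshape = (1, C, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gshape)) * inv_std.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(gshape) * inv_std.reshape(gshape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                gxhat_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gi * (g - gsum / m - xhat * gxhat_sum / m))
            else:
                x._accumulate(gi * g)

    return _make(out, (x, gamma, beta), backward)
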