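"""A compact reverse-mode automatic-differentiation core over NumPy arrays.

The detector is a small convolutional network trained on a CPU, so the
engine favours clarity and exactness over generality: stride-1 same-padded
convolutions (arbitrary dilation), 2x2 max pooling (stride 1 or 2), exact
factor-2 bilinear upsampling, and the usual elementwise/reduction algebra.
Gradients are accumulated by topological traversal of the recorded graph.

All ops preserve the dtype of their inputs, so the same code path runs in
float32 for training and in float64 when checked against brute-force
oracles.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "exp",
    "log",
    "power",
    "sigmoid",
    "relu",
    "clip",
    "matmul",
    "reduce_sum",
    "reduce_mean",
    "reduce_max",
    "reshape",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample2x_bilinear",
]


class Tensor:
    """An n-d array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the Tensor's reflected operator
    __array_ufunc__ = None

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable | None = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # ---- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # ---- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return reduce_max(self, axis, keepdims)

    # ---- reverse pass --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every requiring leaf."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: tuple, backward: Callable) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, True, parents, backward)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---- elementwise -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(out, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _make(out, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def backward(g):
        ga = _unbroadcast(g / b.data, a.shape)
        gb = _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
        return ga, gb

    return _make(out, (a, b), backward)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        return (-g,)

    return _make(-a.data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        return (g * out,)

    return _make(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        return (g / a.data,)

    return _make(np.log(a.data), (a,), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data**p

    def backward(g):
        return (g * p * a.data ** (p - 1),)

    return _make(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g):
        return (g * out * (1.0 - out),)

    return _make(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)

    def backward(g):
        return (g * (a.data > 0),)

    return _make(out, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the active range."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)

    def backward(g):
        return (g * ((a.data >= lo) & (a.data <= hi)),)

    return _make(out, (a,), backward)


# ---- shape / reductions ------------------------------------------------

def reshape(a, shape: tuple) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        return (g.reshape(a.shape),)

    return _make(a.data.reshape(shape), (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return (out,)

    return _make(a.data[idx], (a,), backward)


def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _make(out, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    n = int(np.prod([a.shape[ax] for ax in axes]))
    out = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g / n, a.shape).copy(),)

    return _make(out, (a,), backward)


def reduce_max(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    kept = a.data.max(axis=axes, keepdims=True)
    out = kept if keepdims else kept.reshape(
        tuple(s for i, s in enumerate(a.shape) if i not in axes)
    )

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        mask = a.data == kept
        counts = mask.sum(axis=axes, keepdims=True)
        return (np.broadcast_to(g, a.shape) * mask / counts,)

    return _make(out, (a,), backward)


def concat(tensors: Sequence, axis: int) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(ts), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return g @ b.data.T, a.data.T @ g

    return _make(out, (a, b), backward)


# ---- convolution -------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, d: int, H: int, W: int) -> np.ndarray:
    """Patch matrix (N, C*kh*kw, H*W) of a spatially padded NCHW array.

    Built from kh*kw contiguous slice copies (one per kernel offset), which
    is much cheaper than gathering through a strided window view.
    """
    N, C = xp.shape[:2]
    col = np.empty((N, C, kh, kw, H, W), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[:, :, i * d : i * d + H, j * d : j * d + W]
    return col.reshape(N, C * kh * kw, H * W)


def _conv2d_data(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Forward stride-1 same-padded convolution on raw arrays (no graph)."""
    O, C, kh, kw = w.shape
    d = dilation
    N, _, H, W = x.shape
    if kh == 1 and kw == 1:
        xf = x.reshape(N, C, H * W)
        out = np.matmul(w.reshape(O, C), xf)
        return out.reshape(N, O, H, W), xf
    xp = np.pad(x, ((0, 0), (0, 0), (d * (kh - 1) // 2,) * 2, (d * (kw - 1) // 2,) * 2))
    col = _im2col(xp, kh, kw, d, H, W)
    out = np.matmul(w.reshape(O, -1), col)  # (N, O, H*W)
    return out.reshape(N, O, H, W), col


def conv2d(x, w, b=None, dilation: int = 1) -> Tensor:
    """Cross-correlation (CNN convention), stride 1, same padding, odd kernel.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    O, C, kh, kw = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    if x.ndim != 4 or x.shape[1] != C:
        raise ValueError(f"conv2d input shape {x.shape} incompatible with kernel {w.shape}")
    out, col = _conv2d_data(x.data, w.data, dilation)
    parents = (x, w)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None, None]
        parents = (x, w, b)

    def backward(g):
        N, _, H, W = x.shape
        gf = g.reshape(N, O, H * W)
        gw = np.matmul(gf, col.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        gx = None
        if x.requires_grad:
            # input gradient: correlate g with the flipped, channel-swapped kernel
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx, _ = _conv2d_data(g, np.ascontiguousarray(w_flip), dilation)
        if b is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    return _make(out, parents, backward)


# ---- pooling -----------------------------------------------------------

def maxpool2x2(x, stride: int = 2) -> Tensor:
    """2x2 max pooling. stride=2 halves the map (even sizes required);
    stride=1 keeps the size, padding the bottom/right edge with -inf."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if stride == 2:
        if H % 2 or W % 2:
            raise ValueError("stride-2 2x2 pooling needs even spatial sizes")
        cands = np.stack(
            [x.data[:, :, dh::2, dw::2] for dh in (0, 1) for dw in (0, 1)], axis=0
        )
    elif stride == 1:
        xp = np.pad(x.data, ((0, 0), (0, 0), (0, 1), (0, 1)), constant_values=-np.inf)
        cands = np.stack(
            [xp[:, :, dh : dh + H, dw : dw + W] for dh in (0, 1) for dw in (0, 1)],
            axis=0,
        )
    else:
        raise ValueError("stride must be 1 or 2")
    idx = cands.argmax(axis=0)
    out = np.take_along_axis(cands, idx[None], axis=0)[0]

    def backward(g):
        gx = np.zeros_like(x.data)
        if stride == 2:
            for k, (dh, dw) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
                gx[:, :, dh::2, dw::2] += g * (idx == k)
        else:
            gp = np.zeros((N, C, H + 1, W + 1), dtype=x.dtype)
            for k, (dh, dw) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
                gp[:, :, dh : dh + H, dw : dw + W] += g * (idx == k)
            gx = gp[:, :, :H, :W]
        return (gx,)

    return _make(out, (x,), backward)


# ---- factor-2 bilinear upsampling --------------------------------------
# Half-pixel-centre convention: output sample j reads input coordinate
# (j + 0.5)/2 - 0.5, i.e. even outputs mix rows (m-1, m) with weights
# (1/4, 3/4) and odd outputs mix (m, m+1) with (3/4, 1/4); edges clamp.


def _up_axis(x: np.ndarray) -> np.ndarray:
    """Upsample the last axis from n to 2n."""
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    even = out[..., 0::2]
    odd = out[..., 1::2]
    even[..., 0] = x[..., 0]
    even[..., 1:] = 0.25 * x[..., :-1] + 0.75 * x[..., 1:]
    odd[..., :-1] = 0.75 * x[..., :-1] + 0.25 * x[..., 1:]
    odd[..., -1] = x[..., -1]
    return out


def _down_axis(g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_up_axis` (scatter the 2n gradient back to n)."""
    ge = g[..., 0::2]
    go = g[..., 1::2]
    n = ge.shape[-1]
    out = np.zeros(g.shape[:-1] + (n,), dtype=g.dtype)
    out += 0.75 * ge
    out[..., :-1] += 0.25 * ge[..., 1:]
    out += 0.75 * go
    out[..., 1:] += 0.25 * go[..., :-1]
    out[..., 0] += 0.25 * ge[..., 0]  # edge clamp of output 0
    out[..., -1] += 0.25 * go[..., -1]  # edge clamp of last output
    return out


def upsample2x_bilinear(x) -> Tensor:
    """Bilinear x2 upsampling of an NCHW tensor (half-pixel centres)."""
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError("expected an NCHW tensor")
    data = _up_axis(np.swapaxes(_up_axis(x.data), 2, 3))
    data = np.swapaxes(data, 2, 3)

    def backward(g):
        gx = np.swapaxes(_down_axis(np.swapaxes(g, 2, 3)), 2, 3)
        return (_down_axis(gx),)

    return _make(data, (x,), backward)
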