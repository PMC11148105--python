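"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based engine sufficient for training convolutional
encoder-decoder segmentation networks on the CPU.  Every differentiable
operation builds a node in an implicit DAG; :meth:`Tensor.backward` runs a
topological sweep accumulating gradients into ``Tensor.grad``.

Only the primitives the segmentation model actually needs are provided:
broadcast arithmetic, matmul, elementwise nonlinearities, axis reductions,
shape ops, dilated 2-D convolution with "same" zero padding, 2x2 stride-2
transposed convolution, and 2x2 max pooling.  Convolutions are evaluated by
gathering the (padded) input into a kernel-tap matrix (im2col) and
contracting with ``matmul``, which keeps the hot loops inside BLAS.

The engine is single precision by design: every Tensor holds float32 data
(inputs of any other dtype are converted on construction), so mixed-dtype
expressions can never silently promote the whole graph to float64 and halve
GEMM throughput.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "clip",
    "broadcast_to",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype != DTYPE:
            self.data = self.data.astype(DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ info
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # ------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the tape
        for node in topo:
            node._backward = None
            node._parents = ()

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ------------------------------------------------------------ operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tensor_max(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    out.requires_grad = requires_grad
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ----------------------------------------------------------------- arithmetic
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.shape))
        b._accumulate(_unbroadcast(grad, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad * b.data, a.shape))
        b._accumulate(_unbroadcast(grad * a.data, b.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    data = a.data**p

    def backward(grad):
        a._accumulate(grad * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad @ np.swapaxes(b.data, -1, -2), a.shape))
        b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ grad, b.shape))

    return _make(data, (a, b), backward)


# --------------------------------------------------------------- elementwise
def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(grad):
        a._accumulate(grad * mask)

    return _make(data, (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, slope * a.data)

    def backward(grad):
        a._accumulate(grad * np.where(mask, DTYPE(1.0), DTYPE(slope)))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # exp only of non-positive arguments, so large |x| cannot overflow
    z = np.exp(-np.abs(a.data))
    data = np.where(a.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

    def backward(grad):
        a._accumulate(grad * data * (1.0 - data))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(grad):
        a._accumulate(grad * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(grad):
        a._accumulate(grad / a.data)

    return _make(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside the active range."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(grad):
        a._accumulate(grad * mask)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------- reductions
def tensor_sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def tensor_mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.size / data.size

    def backward(grad):
        g = grad / count
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def tensor_max(a, axis=None, keepdims=False) -> Tensor:
    """Max reduction; ties split gradient equally among the maxima."""
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        d = data
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
            d = np.expand_dims(d, axis)
        mask = (a.data == d).astype(a.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        a._accumulate(mask * g)

    return _make(data, (a,), backward)


# ----------------------------------------------------------------- shape ops
def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(grad):
        a._accumulate(grad.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(grad):
        a._accumulate(grad.transpose(inv))

    return _make(data, (a,), backward)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    data = np.broadcast_to(a.data, shape)

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.shape))

    return _make(data.copy(), (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
            t._accumulate(g)

    return _make(data, tuple(tensors), backward)


# -------------------------------------------------------------- convolutions
def _im2col(xp: np.ndarray, k: int, d: int, H: int, W: int) -> np.ndarray:
    """Dilated kernel-tap matrix of a padded input.

    Returns (N, C*k*k, H*W); row (c, i, j) holds the input values seen by
    kernel tap (i, j) of channel c across all output positions.
    """
    N, C = xp.shape[:2]
    if k == 1:
        return xp.reshape(N, C, H * W)
    col = np.empty((N, C, k, k, H, W), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            col[:, :, i, j] = xp[:, :, i * d : i * d + H, j * d : j * d + W]
    return col.reshape(N, C * k * k, H * W)


def conv2d(x, weight, bias=None, dilation: int = 1) -> Tensor:
    """Dilated 2-D convolution (cross-correlation) with "same" zero padding.

    ``weight`` has shape (C_out, C_in, k, k) with k odd, so the effective
    kernel k + (k-1)(dilation-1) is odd and spatial dims are preserved.
    Evaluated as one batched GEMM over an im2col tap matrix.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, C, H, W = x.shape
    Cout, Cin, k, k2 = weight.shape
    if k != k2 or k % 2 == 0:
        raise ValueError("conv2d requires a square, odd kernel")
    if Cin != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Cin}")
    d = int(dilation)
    pad = ((k - 1) * d) // 2
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    col = _im2col(xp, k, d, H, W)  # (N, C*k*k, H*W)
    wmat = weight.data.reshape(Cout, C * k * k)
    data = np.matmul(wmat, col).reshape(N, Cout, H, W)
    params = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        data = data + bias.data.reshape(1, -1, 1, 1)
        params.append(bias)

    def backward(grad):
        g = grad.reshape(N, Cout, H * W)
        if weight.requires_grad:
            gw = np.matmul(g, col.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcol = np.matmul(wmat.T, g)  # (N, C*k*k, H*W)
            gtaps = gcol.reshape(N, C, k, k, H, W)
            gxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=grad.dtype)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i * d : i * d + H, j * d : j * d + W] += gtaps[:, :, i, j]
            gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
            x._accumulate(gx)

    return _make(data, tuple(params), backward)


def conv_transpose2d(x, weight, bias=None) -> Tensor:
    """2x2, stride-2 transposed convolution (exact spatial doubling).

    ``weight`` has shape (C_in, C_out, 2, 2); output is (N, C_out, 2H, 2W)
    with y[n, o, 2h+i, 2w+j] = sum_c x[n, c, h, w] * weight[c, o, i, j].
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, C, H, W = x.shape
    Cin, Cout, kh, kw = weight.shape
    if (kh, kw) != (2, 2) or Cin != C:
        raise ValueError("conv_transpose2d expects a (C_in, C_out, 2, 2) weight")
    xf = x.data.reshape(N, C, H * W)
    wmat = weight.data.reshape(C, Cout * 4)
    t = np.matmul(wmat.T, xf)  # (N, Cout*4, H*W)
    data = (
        t.reshape(N, Cout, 2, 2, H, W)
        .transpose(0, 1, 4, 2, 5, 3)  # n, o, H, i, W, j
        .reshape(N, Cout, 2 * H, 2 * W)
    )
    params = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        data = data + bias.data.reshape(1, -1, 1, 1)
        params.append(bias)

    def backward(grad):
        g = (
            grad.reshape(N, Cout, H, 2, W, 2)
            .transpose(0, 1, 3, 5, 2, 4)  # n, o, i, j, H, W
            .reshape(N, Cout * 4, H * W)
        )
        if weight.requires_grad:
            gw = np.matmul(xf, g.transpose(0, 2, 1)).sum(axis=0)  # (C, Cout*4)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.matmul(wmat, g).reshape(N, C, H, W)
            x._accumulate(gx)

    return _make(data, tuple(params), backward)


def maxpool2d(x) -> Tensor:
    """2x2 max pooling with stride 2 (H and W must be even)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    windows = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    data = windows.max(axis=(3, 5))
    # routing mask; ties send gradient to the first maximum in scan order
    flat = windows.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    argmax = flat.argmax(axis=-1)

    def backward(grad):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, argmax[..., None], grad[..., None], axis=-1)
        gx = (
            gflat.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        x._accumulate(gx)

    return _make(data, (x,), backward)
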