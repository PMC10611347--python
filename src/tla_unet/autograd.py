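"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the primitives the segmentation network needs:
broadcast arithmetic, matmul, activations, softmax/log, reductions, reshape
and transpose, 2D convolution (stride 1, "same" or valid padding), 2x max
pooling, channel concatenation and separable bilinear resampling. Gradients
are accumulated by topological-order backpropagation from a scalar loss.

The engine is dtype-generic: a graph built from float32 leaves stays float32
end to end (scalar constants never promote), while float64 inputs give full
double-precision gradients for verification. Nothing here is stochastic.
A :class:`Tensor` wraps an ``ndarray`` plus an optional gradient.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack_mean",
    "bilinear_matrix",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.grad is not None})"

    # -- graph plumbing ------------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            # scalar path: no tensor wrap, so float32 graphs stay float32
            other = float(other)
            out_data = self.data + other

            def backward_scalar(g):
                self._accumulate(g)

            return Tensor._make(out_data, (self,), backward_scalar)
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            other = float(other)
            out_data = self.data * other

            def backward_scalar(g):
                self._accumulate(g * other)

            return Tensor._make(out_data, (self,), backward_scalar)
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data ** 2))

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(ga)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(gb)

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities ------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self) -> "Tensor":
        # exact Gaussian-error-linear unit: x * Phi(x)
        phi = 0.5 * (1.0 + _erf(self.data * float(1.0 / np.sqrt(2.0))))
        out_data = self.data * phi

        def backward(g):
            pdf = np.exp(-0.5 * self.data ** 2) * float(1.0 / np.sqrt(2.0 * np.pi))
            self._accumulate(g * (phi + self.data * pdf))

        return Tensor._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                grad = np.broadcast_to(g, self.data.shape)
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_reduce(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # ties share gradient equally (deterministic)
        counts = mask.sum(axis=axis, keepdims=True)
        result = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * mask / counts)

        return Tensor._make(result, (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the two trailing spatial axes symmetrically."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

        def backward(g):
            self._accumulate(g[sl])

        return Tensor._make(out_data, (self,), backward)

    # -- network-specific ops ------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               padding: int = 0) -> "Tensor":
        """2D cross-correlation, stride 1.

        ``self``: (N, C, H, W); ``weight``: (O, C, kh, kw); output
        (N, O, H', W'). im2col + one GEMM; 1x1 kernels skip the im2col.
        """
        x = self.pad2d(padding) if padding else self
        xd = x.data
        n, c, h, w = xd.shape
        o, c2, kh, kw = weight.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        oh, ow = h - kh + 1, w - kw + 1
        wd = weight.data
        p = oh * ow
        if kh == kw == 1:
            cols = xd.reshape(n, c, p)                     # (N, C, P) view
        else:
            cols = np.empty((n, c, kh * kw, p), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    cols[:, :, i * kw + j] = \
                        xd[:, :, i:i + oh, j:j + ow].reshape(n, c, p)
            cols = cols.reshape(n, c * kh * kw, p)
        wmat = wd.reshape(o, c * kh * kw)
        out_data = np.matmul(wmat, cols).reshape(n, o, oh, ow)
        if bias is not None:
            out_data += bias.data.reshape(1, o, 1, 1)

        def backward(g):
            gm = g.reshape(n, o, p)
            if weight.requires_grad:
                gw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(o, c, kh, kw))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, gm)              # (N, C*kh*kw, P)
                if kh == kw == 1:
                    gx = gcols.reshape(n, c, h, w)
                else:
                    gcols = gcols.reshape(n, c, kh * kw, oh, ow)
                    gx = np.zeros((n, c, h, w), dtype=gcols.dtype)
                    for i in range(kh):
                        for j in range(kw):
                            gx[:, :, i:i + oh, j:j + ow] += gcols[:, :, i * kw + j]
                x._accumulate(gx)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._make(out_data, parents, backward)

    def maxpool2x2(self) -> "Tensor":
        """2x2 max pooling, stride 2; spatial dims must be even."""
        n, c, h, w = self.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        windows = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        out_data = windows.max(axis=(3, 5))
        expanded = out_data[:, :, :, None, :, None]
        mask = windows == expanded
        counts = mask.sum(axis=(3, 5), keepdims=True)

        def backward(g):
            gw = g[:, :, :, None, :, None] * mask / counts
            self._accumulate(gw.reshape(n, c, h, w))

        return Tensor._make(out_data, (self,), backward)

    def bilinear_resize(self, out_hw: tuple[int, int]) -> "Tensor":
        """Separable bilinear resampling of the two trailing axes."""
        h_in, w_in = self.shape[-2], self.shape[-1]
        h_out, w_out = out_hw
        if (h_in, w_in) == (h_out, w_out):
            return self
        dt = self.data.dtype
        a = bilinear_matrix(h_in, h_out).astype(dt)   # (h_out, h_in)
        b = bilinear_matrix(w_in, w_out).astype(dt)   # (w_out, w_in)
        out_data = np.matmul(np.matmul(a, self.data), b.T)

        def backward(g):
            self._accumulate(np.matmul(np.matmul(a.T, g), b))

        return Tensor._make(out_data, (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def stack_mean(tensors: Sequence[Tensor], weights: Sequence[float]) -> Tensor:
    """Weighted mean of scalar tensors with weights normalised to sum 1."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(tensors) != len(weights):
        raise ValueError("one weight per tensor required")
    weights = weights / weights.sum()
    total = tensors[0] * float(weights[0])
    for t, w in zip(tensors[1:], weights[1:]):
        total = total + t * float(w)
    return total


def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D linear-interpolation matrix (n_out, n_in), align_corners=False.

    Rows sum to 1, so constants are preserved and resampled attention maps
    stay inside the input's value range.
    """
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m
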