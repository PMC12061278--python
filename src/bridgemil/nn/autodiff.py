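"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small transformer / MLP models on CPU; this module
provides the tensor primitives those models need (broadcasting arithmetic,
matmul with batching, reductions, elementwise nonlinearities, indexing,
concatenation and a depthwise 2-D convolution) together with gradient
accumulation through a topologically-sorted backward pass.

All arrays are float64; computation is deterministic given deterministic
inputs, which the training loop relies on for its reproducibility contract.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        # promote 1-D operands so the backward pass can assume >= 2-D
        if self.ndim == 1:
            return (self.reshape(1, -1) @ other)[0]
        if other.ndim == 1:
            return (self @ other.reshape(-1, 1))[..., 0]

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), bw)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        orig = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def selu(self, alpha: float = 1.6732632423543772,
             scale: float = 1.0507009873554805):
        """Scaled exponential linear unit (the self-normalizing activation)."""
        pos = self.data > 0
        expx = np.exp(np.minimum(self.data, 0.0))
        out_data = scale * np.where(pos, self.data, alpha * (expx - 1.0))

        def bw(g):
            if self.requires_grad:
                self._accum(g * scale * np.where(pos, 1.0, alpha * expx))

        return self._make(out_data, (self,), bw)

    def clip_min(self, lo: float):
        mask = self.data > lo

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), bw)

    # ------------------------------------------------------------ convolution
    def depthwise_conv2d(self, kernel: "Tensor"):
        """Per-channel 2-D convolution with 'same' zero padding.

        self: (H, W, C); kernel: (k, k, C), k odd. Used by the pyramid
        positional encoding on the square token grid.
        """
        x, k = self.data, kernel.data
        ksz = k.shape[0]
        r = ksz // 2
        H, W, C = x.shape
        xp = np.pad(x, ((r, r), (r, r), (0, 0)))
        out = np.zeros_like(x)
        for di in range(ksz):
            for dj in range(ksz):
                out += xp[di:di + H, dj:dj + W, :] * k[di, dj, :]

        def bw(g):
            if self.requires_grad:
                gp = np.pad(g, ((r, r), (r, r), (0, 0)))
                gx = np.zeros_like(x)
                for di in range(ksz):
                    for dj in range(ksz):
                        # mirror offset: output pixel (i,j) drew from
                        # input (i+di-r, j+dj-r)
                        gx += gp[2 * r - di:2 * r - di + H,
                                 2 * r - dj:2 * r - dj + W, :] * k[di, dj, :]
                self._accum(gx)
            if kernel.requires_grad:
                gk = np.zeros_like(k)
                for di in range(ksz):
                    for dj in range(ksz):
                        gk[di, dj, :] = (xp[di:di + H, dj:dj + W, :] * g
                                         ).sum(axis=(0, 1))
                kernel._accum(gk)

        return self._make(out, (self, kernel), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant w.r.t. the gradient, so it is detached
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
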