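"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine carrying exactly the operations the volume
regression network needs: broadcasted arithmetic, matmul, activations,
reductions, 2D convolution (stride 1, same padding, via im2col), 2×2 max
pooling, average pooling and slicing.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological order.

Shapes follow the (N, C, H, W) convention for image tensors.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(p for p in parents if p.requires_grad)
        out = Tensor(data, requires_grad=bool(parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        inv = 1.0 / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * inv, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data * inv * inv, other.shape))

        return Tensor._make(self.data * inv, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accumulate(g * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), bwd)

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), bwd)

    # -- image ops ---------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int = 1):
        """Stride-1 2D convolution, (N,C,H,W) x (O,C,kh,kw) -> (N,O,H',W')."""
        x = self.data
        w = weight.data
        N, C, H, W = x.shape
        O, _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * kh * kw
        )
        out = (cols @ w.reshape(O, -1).T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
        out = out + bias.data.reshape(1, O, 1, 1)

        def bwd(g):
            gflat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
            if weight.requires_grad:
                weight._accumulate((gflat.T @ cols).reshape(w.shape))
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = (gflat @ w.reshape(O, -1)).reshape(N, Ho, Wo, C, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho, j : j + Wo] += gcols[
                            :, :, :, :, i, j
                        ].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(gxp)

        return Tensor._make(out, (self, weight, bias), bwd)

    def maxpool2(self):
        """2×2 max pooling, stride 2; trailing odd row/col dropped."""
        x = self.data
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : H2 * 2, : W2 * 2].reshape(N, C, H2, 2, W2, 2)
        out = xc.max(axis=(3, 5))
        mask = xc == out[:, :, :, None, :, None]

        def bwd(g):
            gx = np.zeros_like(x)
            spread = mask * g[:, :, :, None, :, None]
            gx[:, :, : H2 * 2, : W2 * 2] = spread.reshape(N, C, H2 * 2, W2 * 2)
            self._accumulate(gx)

        return Tensor._make(out, (self,), bwd)

    def avgpool(self, k: int):
        """k×k average pooling, stride k; trailing remainder dropped."""
        if k == 1:
            return self
        x = self.data
        N, C, H, W = x.shape
        H2, W2 = H // k, W // k
        xc = x[:, :, : H2 * k, : W2 * k].reshape(N, C, H2, k, W2, k)
        out = xc.mean(axis=(3, 5))

        def bwd(g):
            gx = np.zeros_like(x)
            gx[:, :, : H2 * k, : W2 * k] = np.broadcast_to(
                g[:, :, :, None, :, None] / (k * k), xc.shape
            ).reshape(N, C, H2 * k, W2 * k)
            self._accumulate(gx)

        return Tensor._make(out, (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate(datas, axis=axis), tensors, bwd)
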