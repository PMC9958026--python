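"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the spectral transformer and the 1D conv nets:
broadcast-aware elementwise ops, batched matmul, softmax / layer-norm /
batch-norm / GELU / ReLU primitives, strided 1D convolution and max-pooling,
and an Adam optimizer.  Gradients are accumulated on ``Tensor.grad`` by
``Tensor.backward()`` via a topological sort of the tape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order of the tape rooted at self
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # release the closure

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise ------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else g * a
            elif a.ndim == 1:
                ga = g @ b.swapaxes(-1, -2)
                gb = np.outer(a, g)
            else:
                ga = g @ b.swapaxes(-1, -2)
                gb = a.swapaxes(-1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int):
        out = self._make(self.data.swapaxes(a, b), (self,), None)
        out._backward = lambda g: self._accumulate(g.swapaxes(a, b))
        return out

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = self._make(x * phi, (self,), None)
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        out._backward = lambda g: self._accumulate(g * (phi + x * pdf))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,), None)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = backward
        return out

    def layer_norm(self, gain: "Tensor", shift: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = self._make(xhat * gain.data + shift.data, (self, gain, shift), None)

        def backward(g):
            d = x.shape[-1]
            dxhat = g * gain.data
            term = dxhat - dxhat.mean(axis=-1, keepdims=True) \
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
            self._accumulate(term * inv)
            axes = tuple(range(g.ndim - 1))
            gain._accumulate((g * xhat).sum(axis=axes))
            shift._accumulate(g.sum(axis=axes))

        out._backward = backward
        return out

    def batch_norm(self, gain: "Tensor", shift: "Tensor", running: dict,
                   train: bool, momentum: float = 0.1, eps: float = 1e-5):
        """Per-channel normalization of (B, C, L) input over batch and length."""
        x = self.data
        axes = (0, 2)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
            n = x.shape[0] * x.shape[2]
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mu.squeeze()
            unbiased = var.squeeze() * (n / max(n - 1, 1))
            running["var"] = (1 - momentum) * running["var"] + momentum * unbiased
        else:
            mu = running["mean"].reshape(1, -1, 1)
            var = running["var"].reshape(1, -1, 1)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        g3 = gain.data.reshape(1, -1, 1)
        out = self._make(xhat * g3 + shift.data.reshape(1, -1, 1),
                         (self, gain, shift), None)

        def backward(g):
            dxhat = g * g3
            if train:
                term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
                    - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
                self._accumulate(term * inv)
            else:
                self._accumulate(dxhat * inv)
            gain._accumulate((g * xhat).sum(axis=axes))
            shift._accumulate(g.sum(axis=axes))

        out._backward = backward
        return out

    # -- signal ops -------------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: int = 0):
        """Cross-correlation of (B, C_in, L) input with (C_out, C_in, k) kernels."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        x = self.data
        w = weight.data
        b_, c_in, length = x.shape
        c_out, c_in_w, k = w.shape
        if c_in != c_in_w:
            raise ValueError("channel mismatch")
        if k > length + 2 * padding:
            raise ValueError("kernel longer than padded input")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding))) if padding else x
        l_out = (length + 2 * padding - k) // stride + 1
        s0, s1, s2 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(b_, c_in, l_out, k), strides=(s0, s1, s2 * stride, s2)
        )
        y = np.einsum("bilk,oik->bol", cols, w, optimize=True)
        if bias is not None:
            y = y + bias.data.reshape(1, -1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = self._make(y, parents, None)

        def backward(g):
            weight._accumulate(np.einsum("bol,bilk->oik", g, cols, optimize=True))
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2)))
            gxp = np.zeros_like(xp)
            # scatter each kernel tap back onto the padded input
            gcols = np.einsum("bol,oik->bilk", g, w, optimize=True)
            for j in range(k):
                gxp[:, :, j : j + stride * l_out : stride] += gcols[:, :, :, j]
            if padding:
                gxp = gxp[:, :, padding:-padding]
            self._accumulate(gxp)

        out._backward = backward
        return out

    def max_pool1d(self, kernel: int, stride: int):
        """Max pooling over the last axis of a (B, C, L) tensor."""
        x = self.data
        b_, c, length = x.shape
        l_out = (length - kernel) // stride + 1
        s0, s1, s2 = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, shape=(b_, c, l_out, kernel), strides=(s0, s1, s2 * stride, s2)
        )
        arg = win.argmax(axis=-1)
        y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        out = self._make(y, (self,), None)

        def backward(g):
            gx = np.zeros_like(x)
            starts = np.arange(l_out) * stride
            idx = starts[None, None, :] + arg
            bi = np.arange(b_)[:, None, None]
            ci = np.arange(c)[None, :, None]
            np.add.at(gx, (bi, ci, idx), g)
            self._accumulate(gx)

        out._backward = backward
        return out

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(before, after)]
        out = self._make(np.pad(self.data, width), (self,), None)

        def backward(g):
            sl = [slice(None)] * (g.ndim - 1) + [
                slice(before, g.shape[-1] - after if after else None)
            ]
            self._accumulate(g[tuple(sl)])

        out._backward = backward
        return out

    def concat_rows(self, other: "Tensor"):
        """Concatenate along axis 1 (token axis of (B, N, D) tensors)."""
        other = self._lift(other)
        n1 = self.data.shape[1]
        out = self._make(np.concatenate([self.data, other.data], axis=1),
                         (self, other), None)

        def backward(g):
            self._accumulate(g[:, :n1])
            other._accumulate(_unbroadcast(g[:, n1:], other.data.shape))

        out._backward = backward
        return out


def cross_entropy_mean(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, C) logits against integer labels.

    Computed via log-sum-exp for stability; gradient is (softmax − onehot)/B.
    """
    z = logits.data
    labels = np.asarray(labels, dtype=int)
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=-1))
    losses = lse - z[np.arange(z.shape[0]), labels]
    out = Tensor(np.asarray(losses.mean(), dtype=z.dtype))
    out.requires_grad = logits.requires_grad
    if out.requires_grad:
        out._parents = (logits,)

        def backward(g):
            soft = np.exp(z - zmax)
            soft /= soft.sum(axis=-1, keepdims=True)
            soft[np.arange(z.shape[0]), labels] -= 1.0
            logits._accumulate(g * soft / z.shape[0])

        out._backward = backward
    return out


class Adam:
    """Adam with the published defaults (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, epsilon
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
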