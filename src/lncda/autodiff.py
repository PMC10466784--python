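"""Minimal reverse-mode automatic differentiation on dense numpy arrays.

The graph encoder and the feed-forward classifier in this package train on
similarity graphs with at most a few hundred nodes, so all operations are
dense and everything fits comfortably in memory.  This module provides the
small set of differentiable primitives those models need (matrix products,
element-wise nonlinearities, masked softmax, a two-channel 1-D convolution)
plus an Adam optimizer.  It is a deliberately small tape-based engine, not a
general tensor library: shapes are whatever numpy broadcasting accepts, and
gradients of broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "sigmoid_np", "stack2", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor._from_op(self.data.T, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.T)
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(grad, self.data.shape)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._from_op(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                a._accum(g)
                b._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._from_op(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._from_op(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                a._accum(g * b.data)
                b._accum(g * a.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._from_op(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                a._accum(g / b.data)
                b._accum(-g * a.data / (b.data ** 2))
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._from_op(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                a._accum(g @ b.data.T)
                b._accum(a.data.T @ g)
            out._backward = backward
        return out

    # -- reductions and nonlinearities ---------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            out._backward = backward
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def relu(self):
        out = Tensor._from_op(np.maximum(self.data, 0.0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0))
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        y = np.where(self.data > 0, self.data, negative_slope * self.data)
        out = Tensor._from_op(y, (self,), None)
        if out.requires_grad:
            def backward(g, a=self, s=negative_slope):
                a._accum(g * np.where(a.data > 0, 1.0, s))
            out._backward = backward
        return out

    def sigmoid(self):
        y = sigmoid_np(self.data)
        out = Tensor._from_op(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor._from_op(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y)
        return out

    def log(self):
        out = Tensor._from_op(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    # -- structured ops -------------------------------------------------------

    def masked_softmax(self, mask: np.ndarray, axis: int = 1) -> "Tensor":
        """Softmax along `axis` restricted to positions where `mask` is True.

        Positions outside the mask get probability exactly 0.  Each slice must
        contain at least one unmasked position.
        """
        logits = np.where(mask, self.data, -np.inf)
        shifted = logits - logits.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._from_op(p, (self,), None)
        if out.requires_grad:
            def backward(g, a=self, p=p, axis=axis):
                dot = (g * p).sum(axis=axis, keepdims=True)
                a._accum(p * (g - dot))
            out._backward = backward
        return out

    def conv1d_same(self, kernel: "Tensor", bias: "Tensor") -> "Tensor":
        """Same-padded 1-D convolution along the last axis.

        `self` has shape (channels, N, F); `kernel` has shape (channels, w);
        `bias` is a scalar.  Channels are summed into a single (N, F) output,
        the 2-channel -> 1-channel combiner used on the encoder layer outputs.
        """
        x = self.data
        k = kernel.data
        channels, n, f = x.shape
        w = k.shape[1]
        left = (w - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (left, w - 1 - left)))
        y = np.zeros((n, f))
        for c in range(channels):
            for t in range(w):
                y += k[c, t] * xp[c, :, t:t + f]
        y = y + bias.data
        out = Tensor._from_op(y, (self, kernel, bias), None)
        if out.requires_grad:
            def backward(g, a=self, kt=kernel, bt=bias, xp=xp, k=k,
                         w=w, f=f, left=left, channels=channels):
                gk = np.zeros_like(k)
                gx = np.zeros_like(xp)
                for c in range(channels):
                    for t in range(w):
                        gk[c, t] = np.sum(g * xp[c, :, t:t + f])
                        gx[c, :, t:t + f] += k[c, t] * g
                a._accum(gx[:, :, left:left + f])
                kt._accum(gk)
                bt._accum(np.array(g.sum()))
            out._backward = backward
        return out

    # -- backward pass --------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def stack2(a: Tensor, b: Tensor) -> Tensor:
    """Stack two equally shaped tensors into a leading channel axis."""
    if a.data.shape != b.data.shape:
        raise ValueError("stack2 requires equal shapes")
    out = Tensor._from_op(np.stack([a.data, b.data]), (a, b), None)
    if out.requires_grad:
        def backward(g, a=a, b=b):
            a._accum(g[0])
            b._accum(g[1])
        out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 targets.

    Computed in the numerically stable log-sum-exp form; the gradient is
    (sigmoid(logits) - targets) / size.
    """
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor._from_op(np.array(loss.mean()), (logits,), None)
    if out.requires_grad:
        def backward(g, a=logits, y=y):
            a._accum(g * (sigmoid_np(a.data) - y) / y.size)
        out._backward = backward
    return out


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function on raw numpy arrays."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
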