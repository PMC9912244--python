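"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the guide-efficiency network needs:
broadcasting arithmetic, matmul, 1-D convolution along the sequence
axis, max-pooling, batch normalization statistics, the LSTM gate
nonlinearities, concatenation and reductions.  Gradients are exact,
which the Integrated-Gradients attribution relies on (the completeness
axiom is checked against true output differences).

Everything is float64 and seeded; two runs with the same seed are
bit-identical.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------- helpers
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # ------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out**2))

        return Tensor(out, parents=(self,), backward=bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out)

        return Tensor(out, parents=(self,), backward=bw)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------- shape / slice
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    def max(self, axis: int):
        """Max over one axis; gradient flows to the (first) argmax."""
        am = np.expand_dims(self.data.argmax(axis=axis), axis)
        out = np.take_along_axis(self.data, am, axis=axis).squeeze(axis)

        def bw(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, am, np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        return Tensor(out, parents=(self,), backward=bw)

    # ------------------------------------------------------------- backward
    def backward(self, grad=None):
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
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=bw)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution along axis 1 with 'same' zero padding.

    x: (B, L, Cin); w: (k, Cin, Cout); b: (Cout) -> (B, L, Cout).
    """
    B, L, Cin = x.data.shape
    k, _, Cout = w.data.shape
    pl = (k - 1) // 2
    pr = k - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, Cin, k)
    out = np.einsum("blik,kio->blo", win, w.data, optimize=True) + b.data

    def bw(g):
        # g: (B, L, Cout)
        dw = np.einsum("blik,blo->kio", win, g, optimize=True)
        db = g.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        tmp = np.einsum("blo,kio->blki", g, w.data, optimize=True)  # (B, L, k, Cin)
        for dk in range(k):
            dxp[:, dk:dk + L, :] += tmp[:, :, dk, :]
        x._accum(dxp[:, pl:pl + L, :])
        w._accum(dw)
        b._accum(db)

    return Tensor(out, parents=(x, w, b), backward=bw)


def maxpool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping max pool along axis 1 (truncates a ragged tail)."""
    B, L, C = x.data.shape
    Lp = L // pool
    view = x.data[:, : Lp * pool, :].reshape(B, Lp, pool, C)
    am = view.argmax(axis=2)  # (B, Lp, C)
    out = np.take_along_axis(view, am[:, :, None, :], axis=2).squeeze(2)

    def bw(g):
        full = np.zeros((B, Lp, pool, C))
        np.put_along_axis(full, am[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, : Lp * pool, :] = full.reshape(B, Lp * pool, C)
        x._accum(dx)

    return Tensor(out, parents=(x,), backward=bw)


class Adam:
    """Adam optimizer on a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD:
    """Plain (optionally momentum) SGD, offered as the alternative optimizer."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.v[i] = self.momentum * self.v[i] - self.lr * p.grad
            p.data += self.v[i]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


OPTIMIZERS = {"adam": Adam, "sgd": SGD}
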