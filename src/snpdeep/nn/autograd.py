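"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Feature matrices here are a few hundred samples by at most a few thousand
SNPs, so a vectorized tape over float64 numpy arrays is fast enough for
every architecture in the zoo (dense, recurrent, convolutional) while
keeping training fully deterministic: no threads, no fused kernels, just
seeded numpy.

Only the operations the zoo needs are implemented.  Gradients through
broadcasting are handled by summing the upstream gradient back down to the
operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that broadcasting added or expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, _prev=(), requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = tuple(_prev)
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._prev)

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the whole tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recurrent graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = _bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1 - s))

        out._backward = _bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad * (1 - t * t))

        out._backward = _bw
        return out

    def square(self):
        out = Tensor(self.data**2, (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad * 2 * self.data)

        out._backward = _bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad * np.sign(self.data))

        out._backward = _bw
        return out

    # -- reductions and shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, pad: int = 0) -> Tensor:
    """1-D convolution (cross-correlation) along the last axis.

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).  With
    ``pad = (K - 1) // 2`` and odd K the output length equals L ("same"
    padding), which the residual blocks rely on for their identity skips.
    """
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad)))
    K = w.data.shape[2]
    windows = np.lib.stride_tricks.sliding_window_view(xd, K, axis=2)  # (N, C_in, L_out, K)
    out_data = np.einsum("nilk,oik->nol", windows, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(out_data, (x, w, b))

    def _bw():
        g = out.grad  # (N, C_out, L_out)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accumulate(np.einsum("nilk,nol->oik", windows, g, optimize=True))
        if x.requires_grad:
            gx = np.zeros_like(xd)
            L_out = g.shape[2]
            for k in range(K):
                gx[:, :, k : k + L_out] += np.einsum("nol,oi->nil", g, w.data[:, :, k], optimize=True)
            if pad:
                gx = gx[:, :, pad:-pad]
            x._accumulate(gx)

    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits, numerically stable.

    Uses the log-sum-exp form ``max(z, 0) - z*y + log(1 + exp(-|z|))``;
    gradient is ``(sigmoid(z) - y) / n``.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    loss_val = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss_val.mean(), (logits,))

    def _bw():
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
            logits._accumulate(out.grad * (s - y) / z.size)

    out._backward = _bw
    return out
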