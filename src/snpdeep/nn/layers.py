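"""Layers, cells and the Adam optimizer used by the model zoo.

All parameters are initialized from a caller-supplied
``numpy.random.Generator`` so that (data, spec, seed) fully determine the
trained model.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity when ``train=False`` or rate 0."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator, train: bool) -> Tensor:
        if not train or self.rate == 0:
            return x
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class Conv1D(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, same: bool = False):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = Tensor(glorot(rng, fan_in, fan_out, shape=(c_out, c_in, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = (kernel - 1) // 2 if same else 0

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b, pad=self.pad)


class GRUCell(Module):
    """Standard GRU: update gate z, reset gate r, candidate state."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.Wz = Tensor(glorot(rng, n_in + units, units), requires_grad=True)
        self.bz = Tensor(np.zeros(units), requires_grad=True)
        self.Wr = Tensor(glorot(rng, n_in + units, units), requires_grad=True)
        self.br = Tensor(np.zeros(units), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_in + units, units), requires_grad=True)
        self.bh = Tensor(np.zeros(units), requires_grad=True)
        self.units = units

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concat([x, h], axis=1)
        z = (xh @ self.Wz + self.bz).sigmoid()
        r = (xh @ self.Wr + self.br).sigmoid()
        xrh = concat([x, r * h], axis=1)
        h_tilde = (xrh @ self.Wh + self.bh).tanh()
        return (Tensor(1.0) - z) * h + z * h_tilde


class LSTMCell(Module):
    """Standard LSTM with forget-gate bias 1 for stable early training."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        def gate(bias0: float = 0.0):
            W = Tensor(glorot(rng, n_in + units, units), requires_grad=True)
            b = Tensor(np.full(units, bias0), requires_grad=True)
            return W, b

        self.Wf, self.bf = gate(1.0)
        self.Wi, self.bi = gate()
        self.Wo, self.bo = gate()
        self.Wc, self.bc = gate()
        self.units = units

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        xh = concat([x, h], axis=1)
        f = (xh @ self.Wf + self.bf).sigmoid()
        i = (xh @ self.Wi + self.bi).sigmoid()
        o = (xh @ self.Wo + self.bo).sigmoid()
        c_tilde = (xh @ self.Wc + self.bc).tanh()
        c_new = f * c + i * c_tilde
        return o * c_new.tanh(), c_new


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
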