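"""Neural-network layers and the Rectified Adam optimizer.

Built on the tape engine in :mod:`sferakit._autodiff`.  Layers follow the
usual conventions: He initialization for convolutions and ReLU linears,
batch normalization with running statistics for inference, LSTM with a
forget-gate bias of one.
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "LSTM",
    "RAdam",
]


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # parameter (de)serialization: stable ordering from parameters()
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean.copy(), m.running_var.copy()])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.copy()
        rest = arrays[len(params) :]
        bns = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        for bn, (rm, rv) in zip(bns, zip(rest[0::2], rest[1::2])):
            bn.running_mean = rm.copy()
            bn.running_var = rv.copy()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.padding = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.weight = Tensor(np.ones(n_ch), requires_grad=True)
        self.bias = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mean.data.reshape(-1) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var
            )
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor(1.0 / std)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / in_dim)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTM(Module):
    """Single-layer unidirectional LSTM over a (T, input) sequence."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        H = hidden_size
        scale = 1.0 / math.sqrt(H)
        self.w_x = Tensor(
            rng.uniform(-scale, scale, size=(input_size, 4 * H)), requires_grad=True
        )
        self.w_h = Tensor(
            rng.uniform(-scale, scale, size=(H, 4 * H)), requires_grad=True
        )
        bias = np.zeros(4 * H)
        bias[H : 2 * H] = 1.0  # forget-gate bias
        self.bias = Tensor(bias, requires_grad=True)
        self.hidden_size = H

    def __call__(self, xs: Tensor) -> Tensor:
        """Run over a (T, input_size) sequence; returns final hidden state (H,)."""
        H = self.hidden_size
        T = xs.shape[0]
        h = Tensor(np.zeros((1, H)))
        c = Tensor(np.zeros((1, H)))
        for t in range(T):
            x_t = xs[t : t + 1]
            gates = x_t @ self.w_x + h @ self.w_h + self.bias
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h.reshape(H)


class RAdam:
    """Rectified Adam: variance-rectified adaptive learning rate."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        b2t = b2**t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            m_hat = m / (1.0 - b1**t)
            if rho_t > 4.0:
                r = math.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                v_hat = np.sqrt(v / (1.0 - b2t))
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat
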