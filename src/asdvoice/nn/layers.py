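"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as `Tensor`s with `requires_grad=True` and are
initialized from an explicit numpy `Generator`, so two modules built from the
same seed are bit-identical.  `training` is an explicit argument to
`forward`, never hidden state: batch norm uses batch statistics (and updates
its running moments) only when `training=True`, and dropout is active only
when `training=True`.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: recursive parameter collection and state snapshots."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                bufs.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        bufs.extend(item.buffers())
        bufs.extend(getattr(self, "_buffers", []))
        return bufs

    def state(self) -> list[np.ndarray]:
        """Copies of all parameters and buffers (for best-epoch snapshots)."""
        return [p.data.copy() for p in self.parameters()] + [b.copy() for b in self.buffers()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params, bufs = self.parameters(), self.buffers()
        if len(state) != len(params) + len(bufs):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state[: len(params)]):
            p.data[...] = s
        for b, s in zip(bufs, state[len(params):]):
            b[...] = s


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = Tensor(glorot_uniform(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm(Module):
    """Batch normalization over axis 0 with running inference statistics."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._buffers = [self.running_mean, self.running_var]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = ad.tmean(x, axis=0, keepdims=True)
            var = ad.tmean(ad.power(x - mu, 2.0), axis=0, keepdims=True)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var[...] = m * self.running_var + (1 - m) * var.data.ravel()
            xhat = (x - mu) / ad.sqrt(var + Tensor(self.eps))
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


class LSTM(Module):
    """Single-direction LSTM; consumes a list of (batch, in_dim) tensors.

    Gates use separate weight matrices (input, forget, cell, output) — at
    8 hidden units the clarity outweighs the fused-matmul speedup.  Forget
    gate bias starts at 1.0, the standard recurrent-initialization trick.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim, self.hidden = in_dim, hidden
        def wx(): return Tensor(glorot_uniform(rng, in_dim, hidden), requires_grad=True)
        def wh(): return Tensor(glorot_uniform(rng, hidden, hidden), requires_grad=True)
        self.W_xi, self.W_hi = wx(), wh()
        self.W_xf, self.W_hf = wx(), wh()
        self.W_xg, self.W_hg = wx(), wh()
        self.W_xo, self.W_ho = wx(), wh()
        self.b_i = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_f = Tensor(np.ones(hidden), requires_grad=True)
        self.b_g = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_o = Tensor(np.zeros(hidden), requires_grad=True)

    def forward(self, steps: list[Tensor]) -> list[Tensor]:
        batch = steps[0].shape[0]
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        outputs = []
        for x in steps:
            i = ad.sigmoid(x @ self.W_xi + h @ self.W_hi + self.b_i)
            f = ad.sigmoid(x @ self.W_xf + h @ self.W_hf + self.b_f)
            g = ad.tanh(x @ self.W_xg + h @ self.W_hg + self.b_g)
            o = ad.sigmoid(x @ self.W_xo + h @ self.W_ho + self.b_o)
            c = f * c + i * g
            h = o * ad.tanh(c)
            outputs.append(h)
        return outputs


class BiLSTM(Module):
    """Bidirectional LSTM returning a fixed-size sequence summary.

    pooling="final": concatenated final forward and backward hidden states.
    pooling="mean": time-mean of the concatenated per-step outputs.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 pooling: str = "final"):
        if pooling not in ("final", "mean"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.fwd = LSTM(in_dim, hidden, rng)
        self.bwd = LSTM(in_dim, hidden, rng)
        self.pooling = pooling
        self.out_dim = 2 * hidden

    def forward(self, steps: list[Tensor]) -> Tensor:
        out_f = self.fwd.forward(steps)
        out_b = self.bwd.forward(steps[::-1])
        if self.pooling == "final":
            return ad.concat([out_f[-1], out_b[-1]], axis=1)
        per_step = [ad.concat([f, b], axis=1)
                    for f, b in zip(out_f, out_b[::-1])]
        total = per_step[0]
        for s in per_step[1:]:
            total = total + s
        return total * Tensor(1.0 / len(per_step))
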