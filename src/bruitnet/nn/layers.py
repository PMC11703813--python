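"""Neural-network layers built on the autodiff tensor.

Seeded initialization throughout: every layer draws its parameters from a
generator handed in at construction, so two models built from the same seed
are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d, max_pool2d


class Module:
    """Base class: parameter registry and train/eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[tuple[str, Tensor]]:
        out = list(self._params.items())
        for cname, child in self._children.items():
            out.extend((f"{cname}.{pname}", p) for pname, p in child.parameters())
        return out

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        out = [(n, b) for n, b in getattr(self, "_buffers", {}).items()]
        for cname, child in self._children.items():
            out.extend((f"{cname}.{n}", b) for n, b in child.buffers())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self._children.values():
            child.set_training(mode)

    def set_dtype(self, dtype) -> None:
        """Cast all parameters and buffers (float32 for fast training)."""
        for _, p in self.parameters():
            p.data = p.data.astype(dtype)
        for owner in self._iter_modules():
            if hasattr(owner, "_buffers"):
                owner._buffers = {k: v.astype(dtype) for k, v in owner._buffers.items()}

    def _iter_modules(self):
        yield self
        for child in self._children.values():
            yield from child._iter_modules()

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{n}": p.data.copy() for n, p in self.parameters()}
        state.update({f"buffer:{n}": b.copy() for n, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.parameters():
            p.data = np.array(state[f"param:{n}"])
        for n, b in self.buffers():
            b[...] = state[f"buffer:{n}"].astype(b.dtype)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = self.register("weight", _he(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = self.register("bias", np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = self.register("weight", rng.uniform(-bound, bound, (in_dim, out_dim)))
        self.bias = self.register("bias", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(channels))
        self.beta = self.register("beta", np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        # bias-corrected exponential averages (Adam-style): with only tens
        # of updates an uncorrected EMA still carries its arbitrary init,
        # which systematically mis-scales inference activations
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.zeros(channels),
            "steps": np.zeros(1),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.astype(self._buffers["running_mean"].dtype)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.astype(self._buffers["running_var"].dtype)
            self._buffers["steps"] += 1
            return x.batch_norm(self.gamma, self.beta, mu, var, self.eps)
        steps = float(self._buffers["steps"][0])
        corr = 1.0 - (1.0 - self.momentum) ** steps if steps > 0 else 1.0
        mean = self._buffers["running_mean"] / corr
        var = self._buffers["running_var"] / corr if steps > 0 else np.ones_like(mean)
        return x.batch_norm(
            self.gamma, self.beta, mean, var, self.eps, stats_are_batch=False,
        )


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Mask drawn from ``rng``."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate).astype(x.data.dtype)
        mask /= np.float32(1.0 - self.rate) if x.data.dtype == np.float32 else (1.0 - self.rate)
        return x * Tensor(mask)


class LSTM(Module):
    """Single-layer LSTM over (N, T, D) input; returns the last hidden state."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + hidden))
        self.w_ih = self.register("w_ih", rng.uniform(-bound, bound, (in_dim, 4 * hidden)))
        self.w_hh = self.register("w_hh", rng.uniform(-bound, bound, (hidden, 4 * hidden)))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.bias = self.register("bias", bias)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        hdim = self.hidden
        h = Tensor(np.zeros((n, hdim), dtype=x.data.dtype))
        c = Tensor(np.zeros((n, hdim), dtype=x.data.dtype))
        for step in range(t):
            xt = x[:, step, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0 * hdim : 1 * hdim].sigmoid()
            f = gates[:, 1 * hdim : 2 * hdim].sigmoid()
            g = gates[:, 2 * hdim : 3 * hdim].tanh()
            o = gates[:, 3 * hdim : 4 * hdim].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class ChannelAttention(Module):
    """CBAM channel branch: dual-pooled shared bottleneck -> sigmoid weights.

    Global average- and max-pooling over the spatial extent each produce a
    C-vector; a shared two-layer bottleneck (C -> C/reduction -> C, ReLU in
    between) maps both; their sum passes through a sigmoid, giving one
    weight in (0, 1) per channel.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if not 1 <= reduction <= channels:
            raise ValueError(f"reduction must be in [1, {channels}], got {reduction}")
        hidden = max(channels // reduction, 1)
        self.fc1 = self.add_child("fc1", Dense(channels, hidden, rng))
        self.fc2 = self.add_child("fc2", Dense(hidden, channels, rng))

    def weights(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> channel weights (N, C, 1, 1), each in (0, 1)."""
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.reshape(n, c, -1).max(axis=2)
        scores = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return scores.sigmoid().reshape(n, c, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


class SpatialAttention(Module):
    """CBAM spatial branch: channel mean/max maps -> k x k conv -> sigmoid."""

    def __init__(self, kernel: int, rng: np.random.Generator, bias: bool = False):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"spatial kernel must be odd, got {kernel}")
        self.conv = self.add_child("conv", Conv2d(2, 1, kernel, rng, bias=bias))

    def weights(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> spatial weights (N, 1, H, W), each in (0, 1)."""
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


class CBAM(Module):
    """Channel attention followed by spatial attention, both multiplicative."""

    def __init__(self, channels: int, reduction: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.channel = self.add_child("channel", ChannelAttention(channels, reduction, rng))
        self.spatial = self.add_child("spatial", SpatialAttention(kernel, rng))

    def __call__(self, x: Tensor) -> Tensor:
        refined = self.channel(x)
        return self.spatial(refined)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[tuple[str, Tensor]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for _, p in params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
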