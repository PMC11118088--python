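"""Module/parameter plumbing and layers on top of the autodiff engine.

Layers operate on channels-last (NHWC) tensors; a 1x1 convolution is a plain
per-pixel linear map and a kxk convolution is computed as k*k shifted matmuls
against a zero-padded input ("same" output size, stride 1).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_F32 = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=_F32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def trunc_normal_(param: Parameter, rng: np.random.Generator, std: float = 0.02) -> None:
    """Truncated-normal fill at +-2 std (resampling tails)."""
    vals = rng.standard_normal(param.data.shape)
    bad = np.abs(vals) > 2.0
    while bad.any():
        vals[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(vals) > 2.0
    param.data = (vals * std).astype(_F32)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Parameter(np.zeros((in_dim, out_dim), dtype=_F32))
        self.bias = Parameter(np.zeros(out_dim, dtype=_F32)) if bias else None

    def init(self, rng: np.random.Generator, std: float = 0.02):
        trunc_normal_(self.weight, rng, std)
        return self

    def forward(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=_F32))
        self.beta = Parameter(np.zeros(dim, dtype=_F32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


class Conv2d(Module):
    """kxk stride-1 'same' convolution on NHWC tensors (zero padding)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, bias: bool = True):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(np.zeros((k, k, in_ch, out_ch), dtype=_F32))
        self.bias = Parameter(np.zeros(out_ch, dtype=_F32)) if bias else None

    def init(self, rng: np.random.Generator, std: float = 0.02):
        trunc_normal_(self.weight, rng, std)
        return self

    def forward(self, x: Tensor) -> Tensor:
        k, p = self.k, self.k // 2
        N, H, W, _ = x.shape
        if k == 1:
            y = ad.matmul(x, self.weight[0, 0])
        else:
            xp = ad.pad_zero(x, p, p)
            wk = ad.split(self.weight.reshape(k * k, self.in_ch, self.out_ch), k * k, axis=0)
            y = None
            for i in range(k):
                for j in range(k):
                    tap = ad.matmul(
                        xp[:, i : i + H, j : j + W, :],
                        wk[i * k + j].reshape(self.in_ch, self.out_ch),
                    )
                    y = tap if y is None else y + tap
        if self.bias is not None:
            y = y + self.bias
        return y


class Mlp(Module):
    """Two-layer perceptron with GELU, applied per token."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def init(self, rng, std=0.02, out_std=None):
        self.fc1.init(rng, std)
        self.fc2.init(rng, out_std if out_std is not None else std)
        return self

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class SGD:
    """Stochastic gradient descent with momentum and decoupled-style weight decay
    applied through the gradient (classic L2 formulation)."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= _F32(self.lr) * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    """Rescale gradients so their global L2 norm is at most max_norm."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = _F32(max_norm / (total + 1e-12))
        for p in params:
            p.grad *= scale
    return total
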