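"""Neural-network building blocks: linear, layer-norm, attention, 3-D convolution.

Modules own :class:`~hdsemg.nn.autograd.Parameter` leaves and are discovered
recursively through attribute traversal, so ``model.parameters()`` returns
every trainable tensor exactly once.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concatenate
from . import functional as F


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped at two standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std)


class Module:
    """Base class with recursive parameter discovery and train/eval state."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, value in vars(self).items():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, eps=self.eps)


def scaled_dot_product_attention(q: Tensor, k: Tensor, v: Tensor,
                                 scale_dim: int) -> Tensor:
    """softmax(Q K^T / sqrt(scale_dim)) V with rows normalized to 1."""
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(float(scale_dim)))
    return F.softmax(scores, axis=-1) @ v


class MultiheadSelfAttention(Module):
    """h parallel attention heads on d/h-dimensional slices, concatenated.

    ``scale`` selects the softmax temperature: ``per-head`` (the standard
    sqrt(d/h)) or ``full-d`` (the literal pre-split sqrt(d)).
    """

    def __init__(self, d: int, h: int, rng: np.random.Generator,
                 scale: str = "per-head"):
        super().__init__()
        if d % h:
            raise ValueError(f"embedding dim {d} not divisible by {h} heads")
        self.d, self.h = d, h
        self.scale_dim = d // h if scale == "per-head" else d
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def forward(self, z: Tensor) -> Tensor:
        b, t, d = z.shape
        h, dh = self.h, self.d // self.h

        def split(x):  # (B,T,d) -> (B,h,T,dh)
            return x.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        out = scaled_dot_product_attention(
            split(self.wq(z)), split(self.wk(z)), split(self.wv(z)),
            self.scale_dim)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(out)


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer:

    z' = MSA(LN(z)) + z,  z_out = MLP(LN(z')) + z'.
    """

    def __init__(self, d: int, h: int, mlp_hidden: int,
                 rng: np.random.Generator, scale: str = "per-head"):
        super().__init__()
        self.norm1 = LayerNorm(d)
        self.msa = MultiheadSelfAttention(d, h, rng, scale=scale)
        self.norm2 = LayerNorm(d)
        self.mlp_in = Linear(d, mlp_hidden, rng)
        self.mlp_out = Linear(mlp_hidden, d, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = self.msa(self.norm1(z)) + z
        return self.mlp_out(F.gelu(self.mlp_in(self.norm2(z)))) + z


class Conv3d(Module):
    """Valid (no padding), stride-1 3-D convolution via index gathering.

    Input (B, C_in, T, H, W) -> output (B, C_out, T-kt+1, H-kh+1, W-kw+1).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel,
                 rng: np.random.Generator):
        super().__init__()
        kt, kh, kw = kernel
        fan_in = in_channels * kt * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_channels, in_channels, kt, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel = (kt, kh, kw)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        b, cin, t, hh, ww = x.shape
        kt, kh, kw = self.kernel
        to, ho, wo = t - kt + 1, hh - kh + 1, ww - kw + 1
        it = (np.arange(to)[:, None, None, None, None, None]
              + np.arange(kt)[None, None, None, :, None, None])
        ih = (np.arange(ho)[None, :, None, None, None, None]
              + np.arange(kh)[None, None, None, None, :, None])
        iw = (np.arange(wo)[None, None, :, None, None, None]
              + np.arange(kw)[None, None, None, None, None, :])
        # (B, Cin, To, Ho, Wo, kt, kh, kw)
        cols = x[:, :, it, ih, iw]
        cols = cols.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            b, to * ho * wo, cin * kt * kh * kw)
        w = self.weight.reshape(self.out_channels, cin * kt * kh * kw)
        out = cols @ w.transpose(1, 0) + self.bias
        return out.reshape(b, to, ho, wo, self.out_channels).transpose(
            0, 4, 1, 2, 3)


class MaxPool3d(Module):
    """Non-overlapping max pooling with per-axis integer factors."""

    def __init__(self, factors):
        super().__init__()
        self.factors = tuple(factors)

    def forward(self, x: Tensor) -> Tensor:
        b, c, t, hh, ww = x.shape
        ft, fh, fw = self.factors
        t2, h2, w2 = t // ft, hh // fh, ww // fw
        x = x[:, :, :t2 * ft, :h2 * fh, :w2 * fw]
        x = x.reshape(b, c, t2, ft, h2, fh, w2, fw)
        for axis in (7, 5, 3):
            x = x.max(axis=axis)
        return x


__all__ = [
    "Module", "Linear", "LayerNorm", "MultiheadSelfAttention", "EncoderLayer",
    "Conv3d", "MaxPool3d", "scaled_dot_product_attention", "trunc_normal",
    "concatenate",
]
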