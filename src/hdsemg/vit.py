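"""Compact vision transformer for windowed HD-sEMG classification.

A window of shape W x N_ch x N_cv is tiled into N = W*N_ch/(H*V) patches of
H x V x N_cv samples, each flattened and linearly projected (no bias) to the
embedding dimension d.  A learnable class token is prepended, a learnable
1-D positional embedding of shape (N+1) x d is added, and the sequence runs
through L pre-norm encoder layers with h-head self-attention.  The head is a
single linear layer reading only the class-token row of the final sequence.

``count_parameters`` gives the closed-form trainable-tensor count and is
asserted (bit-exactly) against model introspection for every standard
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class ModelConfig:
    """Complete architecture description of one transformer variant."""

    d: int = 64                  # embedding dimension
    n_layers: int = 1            # L, encoder layers
    n_heads: int = 8             # h, attention heads
    mlp_hidden: int = 64         # m, MLP hidden units
    patch: tuple[int, int] = (8, 8)   # (H, V): samples x horizontal channels
    n_classes: int = 66          # C
    window: int = 64             # W, samples per window
    n_ch: int = 8                # horizontal channels
    n_cv: int = 8                # vertical channels
    variant: str = "V1"
    attention_scale: str = "per-head"  # or "full-d" for the pre-split sqrt(d)

    def __post_init__(self):
        h, v = self.patch
        if self.d % self.n_heads:
            raise ValueError("d must be divisible by the number of heads")
        if self.window % h or self.n_ch % v:
            raise ValueError(
                f"patch {self.patch} does not tile a {self.window} x "
                f"{self.n_ch} window")
        if self.n_patches < 1:
            raise ValueError("configuration yields no patches")

    @property
    def n_patches(self) -> int:
        h, v = self.patch
        return (self.window * self.n_ch) // (h * v)

    @property
    def patch_dim(self) -> int:
        h, v = self.patch
        return h * v * self.n_cv

    @property
    def seq_len(self) -> int:
        return self.n_patches + 1


def make_patches(window: np.ndarray, patch: tuple[int, int]) -> np.ndarray:
    """Tile (..., W, N_ch, N_cv) into (..., N, H*V*N_cv) patch vectors.

    Non-overlapping tiling over the (time, horizontal-channel) axes, time
    blocks varying slowest; each patch flattened in (time, horizontal,
    vertical) order.  The tiling is exact and invertible.
    """
    h, v = patch
    *lead, w, n_ch, n_cv = window.shape
    if w % h or n_ch % v:
        raise ValueError(f"patch {patch} does not tile window {(w, n_ch)}")
    x = window.reshape(*lead, w // h, h, n_ch // v, v, n_cv)
    x = np.moveaxis(x, -4, -3)          # (..., w//h, n_ch//v, h, v, n_cv)
    n = (w * n_ch) // (h * v)
    return x.reshape(*lead, n, h * v * n_cv)


def unmake_patches(patches: np.ndarray, patch: tuple[int, int],
                   window_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`make_patches` (exact reassembly)."""
    h, v = patch
    w, n_ch, n_cv = window_shape
    *lead, n, _ = patches.shape
    x = patches.reshape(*lead, w // h, n_ch // v, h, v, n_cv)
    x = np.moveaxis(x, -3, -4)
    return x.reshape(*lead, w, n_ch, n_cv)


class GestureTransformer(nn.Module):
    """The windowed-sEMG classifier network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d, n = config.d, config.n_patches
        # patch projection deliberately has no bias and there is no final
        # pre-head normalization: both are required for the closed-form
        # parameter count to hold
        self.patch_proj = nn.Linear(config.patch_dim, d, rng, bias=False)
        self.class_token = nn.Parameter(nn.trunc_normal(rng, (d,)))
        self.pos_embedding = nn.Parameter(nn.trunc_normal(rng, (n + 1, d)))
        self.layers = [nn.EncoderLayer(d, config.n_heads, config.mlp_hidden,
                                       rng, scale=config.attention_scale)
                       for _ in range(config.n_layers)]
        self.head = nn.Linear(d, config.n_classes, rng)

    # -- forward pieces -------------------------------------------------------

    def embed(self, patches) -> Tensor:
        """z_0 = [class token; x^p_1 E; ...; x^p_N E] + E_pos."""
        p = patches if isinstance(patches, Tensor) else Tensor(patches)
        if p.ndim == 2:
            p = p.reshape(1, *p.shape)
        b = p.shape[0]
        tokens = self.patch_proj(p)                       # (B, N, d)
        cls = self.class_token.reshape(1, 1, -1).broadcast_to(
            (b, 1, self.config.d))
        z0 = nn.concatenate([cls, tokens], axis=1)
        return z0 + self.pos_embedding

    def encode(self, windows) -> Tensor:
        """Run windows (B, W, N_ch, N_cv) through embedding and all layers."""
        from .nn import autograd
        data = windows.data if isinstance(windows, Tensor) else \
            np.asarray(windows, dtype=autograd.DTYPE)
        patches = make_patches(data, self.config.patch)
        z = self.embed(patches)
        for layer in self.layers:
            z = layer(z)
        return z

    def class_tokens(self, windows) -> Tensor:
        """Final-layer class-token rows (B, d) -- the pre-head features."""
        return self.encode(windows)[:, 0, :]

    def forward(self, windows) -> Tensor:
        """Logits (B, C) from the class-token row only."""
        return self.head(self.class_tokens(windows))

    def predict(self, windows, batch_size: int = 128) -> np.ndarray:
        """Argmax class per window (ties resolved to the lowest index)."""
        windows = np.asarray(windows)
        if windows.ndim == 3:
            windows = windows[None]
        out = []
        for lo in range(0, windows.shape[0], batch_size):
            logits = self.forward(windows[lo:lo + batch_size]).data
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out)


def count_parameters(config: ModelConfig) -> int:
    """Closed-form trainable parameter count of :class:`GestureTransformer`.

    patch projection (no bias) + class token + positions
    + L * (2 layer norms + 4 d x d projections with bias + 2 MLP linears)
    + linear head.
    """
    d, m, c, ll = config.d, config.mlp_hidden, config.n_classes, config.n_layers
    n = config.n_patches
    per_layer = 4 * d + 4 * (d * d + d) + (d * m + m) + (m * d + d)
    return (config.patch_dim * d          # patch projection, no bias
            + d                           # class token
            + (n + 1) * d                 # positional embedding
            + ll * per_layer
            + d * c + c)                  # head


_PATCH_BY_CHANNELS = {32: (8, 4), 64: (8, 8), 128: (8, 16)}


def standard_configs(name: str, window: int = 64, channels: int = 128,
                     n_classes: int = 66) -> ModelConfig:
    """The studied configurations.

    V1 -- d=64, L=1, h=8, m=64; patch (8,4)/(8,8)/(8,16) for 32/64/128 channels
    V2 -- d=128, L=1, h=8, m=256; same patching
    V3 -- d=64 on a single 8x16 peak-to-peak image, patch (8,8), 2 patches
    instantaneous -- a single 8x8 frame (W=1) as one whole-frame patch
    """
    if name in ("V1", "V2"):
        if channels not in _PATCH_BY_CHANNELS:
            raise ValueError(f"unsupported channel count {channels}")
        patch = _PATCH_BY_CHANNELS[channels]
        d, m = (64, 64) if name == "V1" else (128, 256)
        return ModelConfig(d=d, n_layers=1, n_heads=8, mlp_hidden=m,
                           patch=patch, n_classes=n_classes, window=window,
                           n_ch=channels // 8, n_cv=8, variant=name)
    if name == "V3":
        # 8x16 single-channel image fed as an 8-sample x 16-channel window
        return ModelConfig(d=64, n_layers=1, n_heads=8, mlp_hidden=64,
                           patch=(8, 8), n_classes=n_classes, window=8,
                           n_ch=16, n_cv=1, variant="V3")
    if name == "instantaneous":
        return ModelConfig(d=64, n_layers=1, n_heads=8, mlp_hidden=64,
                           patch=(1, 8), n_classes=n_classes, window=1,
                           n_ch=8, n_cv=8, variant="instantaneous")
    raise ValueError(f"unknown configuration name {name!r}")


def describe_parameters(config: ModelConfig) -> dict:
    """Per-block parameter-count breakdown summing to ``count_parameters``."""
    d, m, c, ll = config.d, config.mlp_hidden, config.n_classes, config.n_layers
    n = config.n_patches
    per_layer = 4 * d + 4 * (d * d + d) + (d * m + m) + (m * d + d)
    parts = {
        "patch_projection": config.patch_dim * d,
        "class_token": d,
        "positional_embedding": (n + 1) * d,
        "encoder_layers": ll * per_layer,
        "head": d * c + c,
    }
    parts["total"] = sum(parts.values())
    return parts
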