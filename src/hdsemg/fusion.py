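"""Macro-micro fusion: combine the windowed-signal transformer with the
motor-unit image transformer.

The macro path classifies raw preprocessed windows; the micro path
classifies per-motor-unit peak-to-peak MUAP images.  After both are trained
independently their weights are frozen and their classification heads
bypassed; per window, the macro class token and the (aggregated) micro
class token are concatenated, expanded to a 1,024-dimensional feature
vector by a fully connected layer, and classified by a final linear layer.
Only the fusion head receives gradients, so the backbone parameters are
unchanged by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F
from .train_eval import TrainConfig, fit_model
from .vit import GestureTransformer, ModelConfig


def micro_model_config(n_ch: int = 16, n_cv: int = 8,
                       n_classes: int = 66) -> ModelConfig:
    """Transformer config for (n_ch x n_cv) single-channel MUAP images.

    The image is fed as an n_cv-sample window of n_ch channels with a
    trailing singleton axis; with the full 16x8 grid this is the 8x16 image
    with patch (8, 8), i.e. two patches plus the class token.
    """
    return ModelConfig(d=64, n_layers=1, n_heads=8, mlp_hidden=64,
                       patch=(min(8, n_cv), min(8, n_ch)), n_classes=n_classes,
                       window=n_cv, n_ch=n_ch, n_cv=1, variant="V3")


def images_to_windows(images: np.ndarray) -> np.ndarray:
    """(n, n_ch, n_cv) peak-to-peak images -> (n, n_cv, n_ch, 1) model input."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    return images.transpose(0, 2, 1)[..., None]


def default_micro_train_config(seed: int = 0) -> TrainConfig:
    """Micro-path training hyperparameters: Adam lr 3e-4, weight decay 1e-3,
    batch 64, 50 epochs."""
    return TrainConfig(epochs=50, batch_size=64, lr=3e-4, weight_decay=1e-3,
                       anneal_after=50, seed=seed)


@dataclass
class FusionConfig:
    feature_dim: int = 1024
    fc_hidden: tuple[int, ...] = ()   # extra FC widths between expansion and head
    mu_aggregation: str = "mean"      # mean | max over per-window MU tokens
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=50, batch_size=64, lr=3e-4, weight_decay=1e-3, anneal_after=50))


def train_micro(images: list, labels: np.ndarray, config: ModelConfig,
                train_config: TrainConfig | None = None
                ) -> tuple[GestureTransformer, list[float]]:
    """Train the micro transformer on per-MU images.

    ``images`` is a per-window list of (n_ch, n_cv) arrays (possibly empty
    for windows without accepted MUs); every image is an independent
    training sample carrying its window's label.
    """
    train_config = train_config or default_micro_train_config()
    flat, flat_labels = [], []
    for imgs, lab in zip(images, labels):
        for img in imgs:
            flat.append(img)
            flat_labels.append(lab)
    if not flat:
        raise ValueError("no MUAP images to train on")
    x = images_to_windows(np.stack(flat))
    y = np.asarray(flat_labels)
    model = GestureTransformer(config, seed=train_config.seed)
    trace = fit_model(model, x, y, train_config)
    return model, trace


def window_micro_token(images, micro: GestureTransformer,
                       mu_aggregation: str = "mean"
                       ) -> tuple[np.ndarray, bool]:
    """Aggregate the micro class tokens of one window's MU images.

    Returns (token, has_mu); windows with no accepted motor units get a
    zero token and has_mu=False.
    """
    if len(images) == 0:
        return np.zeros(micro.config.d), False
    tokens = micro.class_tokens(images_to_windows(np.stack(images))).data
    if mu_aggregation == "max":
        return tokens.max(axis=0), True
    return tokens.mean(axis=0), True


class FusionHead(nn.Module):
    """concat(macro token, micro token) -> 1024-d FC + GELU -> ... -> C logits."""

    def __init__(self, in_dim: int, n_classes: int, config: FusionConfig,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        widths = [in_dim, config.feature_dim, *config.fc_hidden]
        self.fcs = [nn.Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.head = nn.Linear(widths[-1], n_classes, rng)
        self.n_classes = n_classes

    def forward(self, features) -> Tensor:
        z = features if isinstance(features, Tensor) else Tensor(features)
        for fc in self.fcs:
            z = F.gelu(fc(z))
        return self.head(z)


@dataclass
class FusedModel:
    """Frozen macro and micro backbones plus the trained fusion head."""

    macro: GestureTransformer
    micro: GestureTransformer
    head: FusionHead
    config: FusionConfig

    def features(self, windows: np.ndarray, images_per_window: list
                 ) -> np.ndarray:
        """Detached concatenated class tokens, (n, 2d)."""
        macro_tok = self.macro.class_tokens(windows).data
        micro_tok = np.stack([
            window_micro_token(imgs, self.micro,
                               self.config.mu_aggregation)[0]
            for imgs in images_per_window])
        return np.concatenate([macro_tok, micro_tok], axis=1)

    def forward(self, windows: np.ndarray, images_per_window: list) -> Tensor:
        return self.head(self.features(windows, images_per_window))

    def predict(self, windows: np.ndarray, images_per_window: list
                ) -> np.ndarray:
        return np.argmax(self.forward(windows, images_per_window).data, axis=1)


def fuse_and_classify(window: np.ndarray, images: list,
                      macro: GestureTransformer, micro: GestureTransformer,
                      head: FusionHead,
                      config: FusionConfig | None = None) -> np.ndarray:
    """Logits for a single window from the frozen-backbone fused model."""
    fused = FusedModel(macro, micro, head, config or FusionConfig())
    return fused.forward(np.asarray(window)[None], [images]).data[0]


def train_fusion(windows: np.ndarray, images_per_window: list,
                 labels: np.ndarray, macro: GestureTransformer,
                 micro: GestureTransformer,
                 config: FusionConfig | None = None) -> FusedModel:
    """Train the fusion head on frozen-backbone features.

    Class tokens are computed once with gradients detached and only the
    head's parameters are handed to the optimizer, so backbone tensors are
    provably untouched.
    """
    config = config or FusionConfig()
    n_classes = int(labels.max()) + 1
    fused = FusedModel(macro, micro,
                       FusionHead(2 * macro.config.d, n_classes, config,
                                  seed=config.train.seed),
                       config)
    feats = fused.features(windows, images_per_window)
    fit_model(fused.head, feats, np.asarray(labels), config.train)
    return fused
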