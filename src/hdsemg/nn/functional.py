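"""Differentiable composite operations built on the autodiff primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; rows along ``axis`` sum to one."""
    # the running max is piecewise constant, so it is treated as data
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    shifted = x - m
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, exact (erf) form."""
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale + shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    return centered / ((var + eps) ** 0.5) * weight + bias


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``.

    ``logits`` has shape (B, C); ``labels`` is a length-B integer array.
    """
    labels = np.asarray(labels)
    ls = log_softmax(logits, axis=-1)
    picked = ls[np.arange(labels.shape[0]), labels]
    return -picked.mean()


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
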