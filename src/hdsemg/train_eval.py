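"""Training, cross-validation protocols, metrics and statistical comparisons.

Per-subject training uses Adam (beta1 0.9, beta2 0.999), learning rate 1e-4,
weight decay 1e-3, cross-entropy loss, 20 epochs at batch size 128, with the
learning rate annealed after the first 10 epochs.  Evaluation follows the
by-repetition protocol: each of the recorded repetitions serves once as the
held-out test fold and its windows never appear in training.  The shuffled
protocol pools windows across repetitions before splitting and is known to
be optimistic relative to by-repetition cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .nn import Adam, Tensor, annealed_lr
from .nn import functional as F
from .session import WindowedDataset
from .vit import GestureTransformer, ModelConfig


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 128
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-3
    anneal_after: int = 10          # epochs at constant lr before decay
    anneal_schedule: str = "linear"  # or "cosine"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("need at least one epoch")
        # shorter runs than the annealing onset simply never anneal
        self.anneal_after = min(self.anneal_after, self.epochs)


@dataclass
class EvalReport:
    """Fold-wise accuracies and pooled confusion-matrix metrics.

    Confusion counts are summed over folds, then row-normalized; accuracies
    are percentages.
    """

    fold_accuracies: list[float]
    confusion_counts: np.ndarray
    classes: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    @property
    def confusion(self) -> np.ndarray:
        return row_normalize(self.confusion_counts)

    @property
    def metrics(self) -> dict:
        return compute_metrics(self.confusion_counts)


def encode_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary gesture ids onto 0..C-1 (sorted order)."""
    classes, encoded = np.unique(labels, return_inverse=True)
    return encoded, classes


def fit_model(model, windows: np.ndarray, labels: np.ndarray,
              config: TrainConfig) -> list[float]:
    """Adam / cross-entropy training loop; returns the per-epoch mean loss.

    ``model`` is any module mapping a (B, W, N_ch, N_cv) batch to logits.
    Labels must already be encoded to 0..C-1.
    """
    n = windows.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    n_classes = model.config.n_classes if hasattr(model, "config") \
        else int(labels.max()) + 1
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"labels must lie in [0, {n_classes}), got "
            f"[{labels.min()}, {labels.max()}]")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas,
               weight_decay=config.weight_decay)
    trace = []
    for epoch in range(config.epochs):
        opt.lr = annealed_lr(config.lr, epoch, config.epochs,
                             config.anneal_after, config.anneal_schedule)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            opt.zero_grad()
            loss = F.cross_entropy(model(windows[idx]), labels[idx])
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
        trace.append(float(np.mean(losses)))
    return trace


def train_subject(dataset: WindowedDataset, model_config: ModelConfig,
                  train_config: TrainConfig
                  ) -> tuple[GestureTransformer, list[float]]:
    """Train one transformer on a windowed dataset (labels already 0..C-1)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model = GestureTransformer(model_config, seed=train_config.seed)
    trace = fit_model(model, dataset.windows, dataset.labels, train_config)
    return model, trace


def _accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    return 100.0 * float(np.mean(pred == true))


def _confusion_counts(true: np.ndarray, pred: np.ndarray,
                      n_classes: int) -> np.ndarray:
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (true, pred), 1)
    return counts


def crossval_by_repetition(dataset: WindowedDataset,
                           model_config: ModelConfig,
                           train_config: TrainConfig) -> EvalReport:
    """One fold per repetition id; the tested repetition is fully held out."""
    reps = np.unique(dataset.repetitions)
    if len(reps) < 2:
        raise ValueError("by-repetition cross-validation needs >= 2 repetitions")
    labels, classes = encode_labels(dataset.labels)
    cfg = _with_classes(model_config, len(classes))
    accs, counts = [], np.zeros((len(classes), len(classes)), dtype=np.int64)
    for rep in reps:
        test = dataset.repetitions == rep
        model = GestureTransformer(cfg, seed=train_config.seed)
        fit_model(model, dataset.windows[~test], labels[~test], train_config)
        pred = model.predict(dataset.windows[test])
        accs.append(_accuracy(pred, labels[test]))
        counts += _confusion_counts(labels[test], pred, len(classes))
    return EvalReport(fold_accuracies=accs, confusion_counts=counts,
                      classes=classes)


def shuffled_split_eval(dataset: WindowedDataset, model_config: ModelConfig,
                        train_config: TrainConfig, train_fraction: float,
                        seed: int) -> EvalReport:
    """Pool windows across repetitions, shuffle, split, train, evaluate.

    Optimistic relative to by-repetition cross-validation: windows from the
    tested repetitions also appear (at other time offsets) in training.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels, classes = encode_labels(dataset.labels)
    cfg = _with_classes(model_config, len(classes))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(train_fraction * len(dataset)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    model = GestureTransformer(cfg, seed=train_config.seed)
    fit_model(model, dataset.windows[train_idx], labels[train_idx], train_config)
    pred = model.predict(dataset.windows[test_idx])
    counts = _confusion_counts(labels[test_idx], pred, len(classes))
    return EvalReport(fold_accuracies=[_accuracy(pred, labels[test_idx])],
                      confusion_counts=counts, classes=classes)


def _with_classes(cfg: ModelConfig, n_classes: int) -> ModelConfig:
    from dataclasses import replace
    return replace(cfg, n_classes=n_classes) if cfg.n_classes != n_classes else cfg


# -- metrics ------------------------------------------------------------------

def row_normalize(counts: np.ndarray) -> np.ndarray:
    """Row-stochastic confusion matrix; empty rows stay zero."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)


def compute_metrics(confusion_counts: np.ndarray) -> dict:
    """Per-class precision / recall / F1 and the multiclass (generalized) MCC.

    Zero-denominator cases are reported as 0 and flagged in ``degenerate``.
    """
    counts = np.asarray(confusion_counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("confusion counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(counts)
    pred_k = counts.sum(axis=0)     # column sums: predicted per class
    true_k = counts.sum(axis=1)     # row sums: actual per class
    degenerate = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_k > 0, tp / pred_k, 0.0)
        recall = np.where(true_k > 0, tp / true_k, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if np.any(pred_k == 0):
        degenerate.append("precision")
    if np.any(true_k == 0):
        degenerate.append("recall")
    # generalized MCC (R_k statistic) on the pooled count matrix
    c, s = tp.sum(), total
    num = c * s - pred_k @ true_k
    den = np.sqrt(s ** 2 - pred_k @ pred_k) * np.sqrt(s ** 2 - true_k @ true_k)
    if den == 0:
        mcc = 0.0
        degenerate.append("mcc")
    else:
        mcc = float(num / den)
    return {
        "precision": precision, "recall": recall, "f1": f1, "mcc": mcc,
        "accuracy": float(c / s),
        "confusion": row_normalize(counts),
        "degenerate": degenerate,
    }


# -- statistical comparison ---------------------------------------------------

_P_BINS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def annotate_p_value(p: float) -> str:
    """Significance annotation: **** <= 1e-4 < *** <= 1e-3 < ** <= 1e-2
    < * <= 5e-2 < ns."""
    for threshold, stars in _P_BINS:
        if p <= threshold:
            return stars
    return "ns"


def wilcoxon_compare(acc_a, acc_b) -> tuple[float, str]:
    """Two-sided Wilcoxon signed-rank test on paired accuracies."""
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    if np.allclose(a, b):
        warnings.warn("all paired differences are zero; test is degenerate")
        return 1.0, "ns"
    p = float(sp_stats.wilcoxon(a, b).pvalue)
    return p, annotate_p_value(p)


def positional_similarity(model_or_params) -> np.ndarray:
    """Cosine-similarity matrix of the learned patch position rows.

    The class-token row is excluded; zero-norm rows yield 0 entries (flagged
    with a warning).  The diagonal of any nonzero row is exactly 1.
    """
    if isinstance(model_or_params, GestureTransformer):
        pos = model_or_params.pos_embedding.data
    else:
        pos = np.asarray(model_or_params)
    rows = pos[1:]                           # patch rows only
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0):
        warnings.warn("zero-norm position rows; their similarities are set to 0")
    safe = np.where(norms == 0, 1.0, norms)
    unit = rows / safe[:, None]
    sim = unit @ unit.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, np.where(norms == 0, 0.0, 1.0))
    return sim
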