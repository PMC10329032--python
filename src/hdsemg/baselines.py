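"""Feature-based and convolutional baseline classifiers.

TD-PSD features estimate the first spectral moments of the power spectral
density directly in the time domain: by Parseval's theorem the sum of
squares of a signal equals that of its Fourier transform, and successive
discrete derivatives weight the spectrum by rising powers of frequency, so
root-mean-square values of the signal and its differences recover spectral
moments m0..m4 without an explicit transform.  The classical set is the
time-domain quartet RMS / zero crossings / slope-sign changes / waveform
length.  Either set feeds an SVM or LDA evaluated with exactly the same
by-repetition folds as the deep models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn
from .nn import Tensor
from .nn import functional as F
from .session import WindowedDataset
from .train_eval import EvalReport, _accuracy, _confusion_counts, encode_labels


@dataclass
class TDPSDConfig:
    """lambda is the moment-compression exponent; ``derivative_mode`` selects
    how the five RMS roots map onto difference orders (see tdpsd_features)."""

    lam: float = 0.1
    derivative_mode: str = "as-printed"   # or "ordered"

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.derivative_mode not in ("as-printed", "ordered"):
            raise ValueError("derivative_mode must be 'as-printed' or 'ordered'")


def _rms(x: np.ndarray, n: int) -> float:
    """sqrt(sum(x^2) / n) -- the divisor is the original length n."""
    return float(np.sqrt(np.sum(x ** 2) / n))


def tdpsd_features(x: np.ndarray, config: TDPSDConfig | None = None
                   ) -> np.ndarray:
    """Five TD-PSD features {m0, m1-m0, m2, m3-m2, m4-m3} of one channel.

    m_k = root_k^lambda / lambda, where the roots are RMS values of
    discrete differences of the signal.  In ``as-printed`` mode the roots
    are A=RMS(x), B=RMS(dx), C=RMS(d(dx)), D=RMS(d2x), E=RMS(d(d2x)) with
    d the forward difference -- under which C and D coincide and the
    m3-m2 feature is identically zero (an algebraic consequence of that
    formulation, kept for fidelity).  ``ordered`` mode maps the roots onto
    difference orders 0..4, which removes the degeneracy.
    """
    config = config or TDPSDConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for third differences")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    d3 = np.diff(d2)
    if config.derivative_mode == "as-printed":
        roots = [_rms(x, n), _rms(d1, n), _rms(np.diff(d1), n),
                 _rms(d2, n), _rms(np.diff(d2), n)]
    else:
        d4 = np.diff(d3)
        roots = [_rms(x, n), _rms(d1, n), _rms(d2, n),
                 _rms(d3, n), _rms(d4, n)]
    lam = config.lam
    m = [r ** lam / lam for r in roots]
    return np.array([m[0], m[1] - m[0], m[2], m[3] - m[2], m[4] - m[3]])


def classical_features(x: np.ndarray) -> np.ndarray:
    """RMS, zero crossings, slope-sign changes, waveform length.

    ZC counts strict sign changes (zero samples break a crossing); SSC
    counts strict slope-sign changes; WL is the total variation sum |dx|.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    rms = float(np.sqrt(np.mean(x ** 2)))
    zc = int(np.sum(x[:-1] * x[1:] < 0))
    d = np.diff(x)
    ssc = int(np.sum(d[:-1] * d[1:] < 0))
    wl = float(np.sum(np.abs(d)))
    return np.array([rms, zc, ssc, wl])


def feature_matrix(dataset: WindowedDataset, kind: str,
                   tdpsd: TDPSDConfig | None = None) -> np.ndarray:
    """Per-window feature vectors, features concatenated over channels.

    kind -- "tdpsd" (5 features/channel) or "classical" (4 features/channel)
    """
    extract = (lambda x: tdpsd_features(x, tdpsd)) if kind == "tdpsd" \
        else classical_features
    n, w = dataset.windows.shape[:2]
    flat = dataset.windows.reshape(n, w, -1)
    return np.stack([
        np.concatenate([extract(flat[i, :, c]) for c in range(flat.shape[2])])
        for i in range(n)])


def fit_baseline(features: np.ndarray, labels: np.ndarray,
                 repetitions: np.ndarray, kind: str,
                 seed: int = 0) -> tuple[object, EvalReport]:
    """By-repetition cross-validation of an SVM (RBF) or LDA classifier.

    Features are standardized per training fold.  A singular within-class
    covariance in LDA falls back to shrinkage estimation with a warning.
    The folds are identical to those the deep models use: each repetition
    id is tested once, trained on the rest.
    """
    if kind not in ("svm", "lda"):
        raise ValueError("kind must be 'svm' or 'lda'")
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    labels, classes = encode_labels(np.asarray(labels))
    reps = np.unique(repetitions)
    if len(reps) < 2:
        raise ValueError("need >= 2 repetitions for cross-validation")
    accs, counts = [], np.zeros((len(classes), len(classes)), dtype=np.int64)
    clf = None
    for rep in reps:
        test = repetitions == rep
        scaler = StandardScaler().fit(features[~test])
        x_train, x_test = scaler.transform(features[~test]), \
            scaler.transform(features[test])
        if kind == "svm":
            clf = SVC(kernel="rbf", random_state=seed)
            clf.fit(x_train, labels[~test])
        else:
            clf = LinearDiscriminantAnalysis()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", RuntimeWarning)
                    clf.fit(x_train, labels[~test])
            except (np.linalg.LinAlgError, RuntimeWarning):
                warnings.warn("singular within-class covariance; "
                              "falling back to shrinkage LDA")
                clf = LinearDiscriminantAnalysis(solver="lsqr",
                                                 shrinkage="auto")
                clf.fit(x_train, labels[~test])
        pred = clf.predict(x_test)
        accs.append(_accuracy(pred, labels[test]))
        counts += _confusion_counts(labels[test], pred, len(classes))
    return clf, EvalReport(fold_accuracies=accs, confusion_counts=counts,
                           classes=classes)


class Cnn3d(nn.Module):
    """Two 3-D convolution blocks (16 then 32 filters of size (5,3,3), GELU,
    dropout, time-axis max pooling) followed by 256- and 128-unit FC layers
    and a linear head.  Stride 1, valid convolutions.
    """

    def __init__(self, window_shape: tuple[int, int, int], n_classes: int,
                 seed: int = 0, dropout: float = 0.2):
        super().__init__()
        w, n_ch, n_cv = window_shape
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv3d(1, 16, (5, 3, 3), rng)
        self.conv2 = nn.Conv3d(16, 32, (5, 3, 3), rng)
        self.pool = nn.MaxPool3d((2, 1, 1))
        t1 = (w - 4) // 2            # conv1 valid + time pool
        t2 = (t1 - 4) // 2           # conv2 valid + time pool
        flat = 32 * t2 * (n_ch - 4) * (n_cv - 4)
        if flat <= 0:
            raise ValueError(f"window shape {window_shape} too small for "
                             "two (5,3,3) valid convolutions")
        self.fc1 = nn.Linear(flat, 256, rng)
        self.fc2 = nn.Linear(256, 128, rng)
        self.head = nn.Linear(128, n_classes, rng)
        self.dropout = dropout
        self._rng = rng
        self.window_shape = window_shape
        self.n_classes = n_classes

    def forward(self, windows) -> Tensor:
        x = windows if isinstance(windows, Tensor) else Tensor(
            np.asarray(windows, dtype=np.float64))
        b = x.shape[0]
        x = x.reshape(b, 1, *x.shape[1:])
        for conv in (self.conv1, self.conv2):
            x = F.gelu(conv(x))
            x = F.dropout(x, self.dropout, self._rng, self.training)
            x = self.pool(x)
        x = x.reshape(b, -1)
        x = F.gelu(self.fc1(x))
        x = F.gelu(self.fc2(x))
        return self.head(x)


def cnn3d_model(window_shape: tuple[int, int, int], n_classes: int,
                seed: int = 0, dropout: float = 0.2) -> Cnn3d:
    """Build the 3-D CNN baseline for (W, n_ch, n_cv) windows."""
    return Cnn3d(window_shape, n_classes, seed=seed, dropout=dropout)
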