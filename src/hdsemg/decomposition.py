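"""Motor-unit decomposition of windowed HD-sEMG and MUAP imaging.

The micro pathway treats the multichannel signal as a convolutive mixture of
motor-unit spike trains.  The blind-source-separation stage follows the
standard EMG decomposition contract: channel extension with delayed copies,
whitening, then deflationary fixed-point ICA; candidate sources are turned
into spike trains by peak picking on the squared source followed by a
two-means split of peak amplitudes, and a source is accepted only when the
silhouette of that split clears a quality threshold (0.92 by default, on the
raw [-1, 1] silhouette scale).  Accepted sources are summarized by
spike-triggered averaging (20-sample window) into per-channel MUAP
templates, whose per-channel peak-to-peak values form the 2-D images the
micro classifier consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal


@dataclass
class DecompositionConfig:
    max_sources: int = 7             # max new-source attempts (and accept bound)
    silhouette_threshold: float = 0.92
    extension_factor: int = 10       # R delayed copies per channel
    sta_window: int = 20             # samples averaged around each spike
    seed: int = 0
    contrast: str = "skew"           # fixed-point nonlinearity: skew | cube | logcosh
    max_iter: int = 100
    tol: float = 1e-6
    min_peak_distance: int = 10      # samples between candidate spikes
    min_spikes: int = 4              # fewer detected firings -> source rejected
    refine_rounds: int = 3           # spike-triggered re-estimations of w
    whiten_shrinkage: float = 0.0    # covariance shrinkage toward the sphere
    sil_scale: str = "raw"           # raw [-1,1] or unit [0,1]

    def __post_init__(self):
        if self.max_sources < 1:
            raise ValueError("max_sources must be >= 1")
        if not 0.0 < self.silhouette_threshold < 1.0:
            raise ValueError("silhouette threshold must lie in (0, 1)")
        if self.extension_factor < 0:
            raise ValueError("extension factor must be >= 0")


@dataclass
class MUDecomposition:
    """Accepted motor units: spike trains, quality scores, unmixing vectors."""

    spike_trains: list
    silhouettes: list
    separation_vectors: list

    @property
    def n_sources(self) -> int:
        return len(self.spike_trains)


@dataclass
class MUAPImage:
    """Per-channel peak-to-peak map of one motor unit's MUAP templates."""

    peak_to_peak: np.ndarray   # (n_ch, n_cv), >= 0
    source_id: int = 0


def _flatten_channels(window: np.ndarray) -> np.ndarray:
    """(W, n_ch, n_cv) -> (channels, time)."""
    window = np.asarray(window, dtype=float)
    if window.ndim == 3:
        w = window.shape[0]
        return window.reshape(w, -1).T
    if window.ndim == 2:
        return window
    raise ValueError("expected a (W, n_ch, n_cv) window or a (channels, T) matrix")


def extend_and_whiten(window: np.ndarray, r: int, rank_tol: float = 1e-8,
                      shrinkage: float = 0.0) -> tuple[np.ndarray, dict]:
    """Extend each channel with R delayed copies, center, and whiten.

    Returns the whitened observation matrix Z with covariance ~ identity,
    plus the whitening transform (for diagnostics).  Z has
    n_channels*(R+1) rows when the extended covariance has full rank;
    rank-deficient directions (eigenvalues below ``rank_tol`` times the
    largest) are dropped with a warning, which both regularizes the problem
    and avoids amplifying numerical noise in noise-free mixtures.

    ``shrinkage`` blends the sample covariance toward the sphere
    (tr(C)/M * I).  Exact whitening over-fits when the window is short
    relative to the extended dimension and then equalizes the signal and
    noise subspaces; partial whitening keeps the motor-unit directions
    dominant, which is essential when decomposing sub-second windows.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    x = _flatten_channels(window)
    n_ch, t = x.shape
    if t <= r:
        raise ValueError(f"window length {t} must exceed extension factor {r}")
    rows = [x[:, r - d:t - d] for d in range(r + 1)]
    ext = np.concatenate(rows, axis=0)               # (n_ch*(R+1), T-R)
    mean = ext.mean(axis=1)
    ext = ext - mean[:, None]
    cov = ext @ ext.T / ext.shape[1]
    if shrinkage > 0.0:
        m = cov.shape[0]
        cov = (1.0 - shrinkage) * cov \
            + shrinkage * (np.trace(cov) / m) * np.eye(m)
    eigval, eigvec = np.linalg.eigh(cov)
    keep = eigval > rank_tol * eigval.max()
    if not keep.all():
        warnings.warn(
            f"rank-deficient extended covariance; keeping {keep.sum()} of "
            f"{len(eigval)} components")
    whitener = (eigvec[:, keep] / np.sqrt(eigval[keep])).T   # (rank, M)
    z = whitener @ ext
    return z, {"whitener": whitener, "mean": mean,
               "eigenvalues": eigval[keep]}


def two_means_split(values: np.ndarray, max_iter: int = 100
                    ) -> tuple[np.ndarray, float, float]:
    """1-D 2-means: returns boolean high-cluster mask and the two centers."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if lo == hi:
        return np.zeros(len(values), dtype=bool), lo, hi
    c_lo, c_hi = lo, hi
    for _ in range(max_iter):
        high = np.abs(values - c_hi) < np.abs(values - c_lo)
        if not high.any() or high.all():
            break
        new_lo, new_hi = values[~high].mean(), values[high].mean()
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    return high, c_lo, c_hi


def silhouette_score(values: np.ndarray, high: np.ndarray,
                     scale: str = "raw") -> float:
    """Mean silhouette of a two-cluster split of scalar amplitudes.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean within-cluster
    distance (0 for singletons) and b_i the mean distance to the other
    cluster; averaged over points.  ``scale="unit"`` maps the result to
    [0, 1] via (s + 1) / 2.  An empty cluster scores 0.
    """
    values = np.asarray(values, dtype=float)
    high = np.asarray(high, dtype=bool)
    if not high.any() or high.all():
        return 0.0
    s_total = 0.0
    for mask in (high, ~high):
        own, other = values[mask], values[~mask]
        for v in own:
            a = np.abs(own - v).sum() / (len(own) - 1) if len(own) > 1 else 0.0
            b = np.abs(other - v).mean()
            s_total += (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    s = s_total / len(values)
    return (s + 1.0) / 2.0 if scale == "unit" else s


def _fixed_point_ica(z: np.ndarray, w0: np.ndarray,
                     previous: list[np.ndarray],
                     config: DecompositionConfig) -> np.ndarray:
    """One deflationary fixed-point ICA vector on whitened data."""
    m, t = z.shape
    basis = np.array(previous) if previous else None

    def deflate(v):
        if basis is not None:
            v = v - basis.T @ (basis @ v)
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    w = deflate(w0)
    for _ in range(config.max_iter):
        s = w @ z
        if config.contrast == "logcosh":
            g, gp = np.tanh(s), 1.0 - np.tanh(s) ** 2
            w_new = z @ g / t - gp.mean() * w
        elif config.contrast == "cube":  # kurtosis
            w_new = z @ (s ** 3) / t - 3.0 * w
        else:  # skewness: the standard contrast for positive spiky sources
            w_new = z @ (s ** 2) / t - 2.0 * s.mean() * w
        w_new = deflate(w_new)
        if abs(abs(w_new @ w)) > 1.0 - config.tol:
            w = w_new
            break
        w = w_new
    return w


def _detect_spikes(source: np.ndarray, config: DecompositionConfig
                   ) -> tuple[np.ndarray, float]:
    """Peak picking on the squared source + two-means amplitude gate."""
    energy = source ** 2
    peaks, _ = sp_signal.find_peaks(energy, distance=config.min_peak_distance)
    if len(peaks) < 4:
        return np.array([], dtype=int), 0.0
    heights = energy[peaks]
    high, _, _ = two_means_split(heights)
    if not high.any() or high.all():
        return np.array([], dtype=int), 0.0
    sil = silhouette_score(heights, high, scale=config.sil_scale)
    return peaks[high], sil


def _overlap_fraction(a: np.ndarray, b: np.ndarray, tol: int = 1,
                      max_lag: int = 15) -> float:
    """Best-lag fraction of spikes in the smaller train matched at +-tol.

    Blind sources are recovered at arbitrary delays within the extension
    range, so duplicates are detected up to a constant lag.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for lag in range(-max_lag, max_lag + 1):
        hits = sum(1 for t in short + lag if np.abs(long_ - t).min() <= tol)
        best = max(best, hits / len(short))
    return best


def extract_musts(z: np.ndarray, config: DecompositionConfig
                  ) -> MUDecomposition:
    """Extract up to ``max_sources`` motor-unit spike trains from whitened data.

    Each new-source attempt (i) initializes the separation vector at the
    highest-energy still-unused observation column -- anchoring the search on
    an actual activity burst -- (ii) runs deflationary fixed-point ICA to
    convergence, (iii) re-estimates the vector a few times as the mean of
    the whitened columns at the detected firing instants (a spike-triggered
    update that only survives for repeatable sources), and (iv) accepts the
    source iff its two-means silhouette clears the threshold, it fired at
    least ``min_spikes`` times, and it is not a duplicate (> 50% best-lag
    overlap) of an earlier source.
    """
    m, t = z.shape
    energy = (z ** 2).sum(axis=0)
    used = np.zeros(t, dtype=bool)
    tried: list[np.ndarray] = []
    accepted: list[np.ndarray] = []
    trains: list[np.ndarray] = []
    sils: list[float] = []
    keep_w: list[np.ndarray] = []

    def mask_spikes(indices):
        half = config.min_peak_distance
        for s in np.clip(indices, 0, t - 1):
            used[max(0, s - half):s + half] = True

    def deflate_accepted(v):
        if accepted:
            basis = np.array(accepted)
            v = v - basis.T @ (basis @ v)
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    for _ in range(config.max_sources):
        masked = np.where(used, -np.inf, energy)
        t0 = int(np.argmax(masked))
        if not np.isfinite(masked[t0]):
            break
        mask_spikes([t0])
        w = _fixed_point_ica(z, z[:, t0], tried, config)
        spikes, sil = _detect_spikes(w @ z, config)
        for _ in range(config.refine_rounds):
            if len(spikes) < 2:
                break
            w_new = deflate_accepted(z[:, spikes].mean(axis=1))
            if not np.any(w_new):
                break
            w = w_new
            spikes, sil = _detect_spikes(w @ z, config)
        tried.append(w)
        mask_spikes(spikes)
        if sil < config.silhouette_threshold or len(spikes) < config.min_spikes:
            continue
        if any(_overlap_fraction(spikes, tr) > 0.5 for tr in trains):
            continue
        trains.append(spikes)
        sils.append(float(sil))
        keep_w.append(w)
        accepted.append(w)
    return MUDecomposition(spike_trains=trains, silhouettes=sils,
                           separation_vectors=keep_w)


def spike_triggered_average(window: np.ndarray, spikes: np.ndarray,
                            sta_window: int = 20) -> np.ndarray:
    """Average ``sta_window``-sample segments centered on each spike.

    ``window`` is the raw (W, n_ch, n_cv) signal; returns templates of shape
    (n_ch, n_cv, sta_window).  Segments clipped by the window boundary are
    dropped; duplicate spike indices count once.  With no usable spike the
    template is zero (flagged with a warning).
    """
    spikes = np.unique(np.asarray(spikes, dtype=int))
    if spikes.size == 0:
        raise ValueError("spike-triggered averaging needs at least one spike")
    window = np.asarray(window, dtype=float)
    w, n_ch, n_cv = window.shape
    half = sta_window // 2
    lo, hi = spikes - half, spikes - half + sta_window
    usable = spikes[(lo >= 0) & (hi <= w)]
    if usable.size == 0:
        warnings.warn("all spikes fall too close to the window boundary; "
                      "returning a zero template")
        return np.zeros((n_ch, n_cv, sta_window))
    segments = np.stack([window[t - half:t - half + sta_window]
                         for t in usable])          # (n, sta, n_ch, n_cv)
    return segments.mean(axis=0).transpose(1, 2, 0)


def peak_to_peak_image(templates: np.ndarray, source_id: int = 0) -> MUAPImage:
    """Per-channel max - min of the STA templates; invariant to DC offsets."""
    templates = np.asarray(templates, dtype=float)
    if not np.all(np.isfinite(templates)):
        raise ValueError("templates must be finite")
    return MUAPImage(peak_to_peak=templates.max(axis=-1) - templates.min(axis=-1),
                     source_id=source_id)


def decompose_window(window: np.ndarray, config: DecompositionConfig
                     ) -> tuple[MUDecomposition, list[MUAPImage]]:
    """Full micro front end: whiten, extract spike trains, build MUAP images.

    Spike indices live on the extended-time axis and each blind source is
    recovered at an unknown delay within the extension range, so the raw
    window is aligned per source by the offset (0..R) that maximizes the
    energy of the spike-triggered average.
    """
    window = np.asarray(window, dtype=float)
    z, _ = extend_and_whiten(window, config.extension_factor,
                             shrinkage=config.whiten_shrinkage)
    decomp = extract_musts(z, config)
    r = config.extension_factor
    images = []
    for k, spikes in enumerate(decomp.spike_trains):
        best, best_energy = None, -1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for offset in range(r + 1):
                tmpl = spike_triggered_average(window, spikes + r - offset,
                                               config.sta_window)
                energy = float((tmpl ** 2).sum())
                if energy > best_energy:
                    best, best_energy = tmpl, energy
        images.append(peak_to_peak_image(best, source_id=k))
    return decomp, images


def match_spike_trains(estimated: np.ndarray, truth: np.ndarray,
                       tol: int = 1, max_lag: int = 30) -> float:
    """Best-lag F1 between an estimated and a ground-truth spike train.

    A blind source is recovered up to an unknown delay, so the alignment lag
    is chosen (within +-max_lag) to maximize agreement; spikes then match
    greedily at +-tol samples.
    """
    est, tr = np.asarray(estimated, int), np.asarray(truth, int)
    if len(est) == 0 or len(tr) == 0:
        return 0.0
    best = 0.0
    for lag in range(-max_lag, max_lag + 1):
        shifted = est + lag
        used = np.zeros(len(tr), dtype=bool)
        hits = 0
        for t in shifted:
            d = np.abs(tr - t)
            d[used] = tol + 1
            j = int(np.argmin(d))
            if d[j] <= tol:
                used[j] = True
                hits += 1
        precision = hits / len(est)
        recall = hits / len(tr)
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best
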