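"""Preprocessing chain for HD-sEMG sessions.

The fixed pipeline order is: full-wave rectification -> first-order
Butterworth low-pass envelope -> amplitude scaling to [-1, 1] -> mu-law
companding -> rest removal -> channel subsetting -> sliding-window
segmentation.  Rectification followed by a 1 Hz low-pass yields the linear
envelope of the signal; mu-law then expands the small amplitudes that carry
most of the gesture information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .session import REST_LABEL, RecordingSession, WindowSpec, WindowedDataset
from .io import load_session, save_session  # re-exported session I/O

__all__ = [
    "NormalizationConfig", "WindowSpec", "WindowedDataset", "RecordingSession",
    "load_session", "save_session", "rectify", "envelope_filter",
    "mu_law_normalize", "scale_to_unit", "remove_rest", "select_channels",
    "segment_windows", "preprocess_session", "moving_average_window_ms",
]


@dataclass
class NormalizationConfig:
    """Envelope and companding parameters.

    mu           -- companding strength; larger values expand small amplitudes more
    cutoff_hz    -- envelope low-pass cutoff (1, 5 and 10 Hz are the studied variants)
    filter_order -- Butterworth order (first order by default)
    zero_phase   -- apply the filter forward-backward instead of causally
    """

    mu: float = 255.0
    cutoff_hz: float = 1.0
    filter_order: int = 1
    zero_phase: bool = False

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff frequency must be positive")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(x)


def envelope_filter(x: np.ndarray, cfg: NormalizationConfig, fs: float,
                    axis: int = 0) -> np.ndarray:
    """Low-pass Butterworth envelope filter applied independently per channel.

    Causal single pass by default (real-time compatible); forward-backward
    (zero-phase) when ``cfg.zero_phase``.  Unit DC gain.
    """
    if cfg.cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cfg.cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = sp_signal.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=fs)
    if cfg.zero_phase:
        return sp_signal.filtfilt(b, a, x, axis=axis)
    return sp_signal.lfilter(b, a, x, axis=axis)


def mu_law_normalize(x: np.ndarray, mu: float = 255.0) -> np.ndarray:
    """mu-law companding F(x) = sign(x) ln(1 + mu|x|) / ln(1 + mu).

    An odd, strictly increasing map of [-1, 1] onto itself; inputs must be
    pre-scaled to [-1, 1] (see :func:`scale_to_unit`).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    x = np.asarray(x)
    if np.abs(x).max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("mu-law input must be scaled to [-1, 1] first")
    return np.sign(x) * np.log1p(mu * np.abs(x)) / np.log1p(mu)


def scale_to_unit(x: np.ndarray, per_channel: bool = True,
                  reference: np.ndarray | None = None) -> np.ndarray:
    """Scale into [-1, 1] by the max absolute value.

    per_channel -- scale each channel by its own max |x| (default) or use a
                   single global factor
    reference   -- boolean mask over samples restricting where the max is
                   taken (e.g. a training portion); defaults to all samples
    """
    ref = x if reference is None else x[reference]
    if per_channel:
        denom = np.abs(ref).max(axis=0, keepdims=True)
    else:
        denom = np.abs(ref).max()
    denom = np.where(denom == 0, 1.0, denom)
    return x / denom


def remove_rest(session: RecordingSession) -> RecordingSession:
    """Drop all rest-labeled samples, keeping gesture/repetition labels.

    Windows are later segmented per contiguous (gesture, repetition) run, so
    no window ever straddles the splice points this introduces.
    """
    keep = session.label != REST_LABEL
    if not keep.any():
        warnings.warn("session contains only rest samples; output is empty")
    return RecordingSession(
        emg=session.emg[keep], fs=session.fs, label=session.label[keep],
        repetition=session.repetition[keep], subject_id=session.subject_id,
        grid=session.grid)


_FRACTIONS = {1: 1, 1.0: 1, "full": 1,
              0.5: 2, "half": 2,
              0.25: 4, "quarter": 4}


def select_channels(session: RecordingSession, fraction) -> RecordingSession:
    """Decimate the stacked-grid row axis, keeping every 2nd or 4th row.

    ``fraction`` is 1, 1/2 or 1/4 (or "full" / "half" / "quarter"); columns
    (the vertical channels) are always kept, so a 16x8 grid becomes 8x8 or
    4x8 while still covering the whole recorded area.
    """
    if fraction not in _FRACTIONS:
        raise ValueError(f"unsupported channel fraction {fraction!r}; "
                         "use 1, 1/2 or 1/4")
    step = _FRACTIONS[fraction]
    rows = session.grid[0]
    if rows % step:
        raise ValueError(f"{rows} rows not divisible by decimation step {step}")
    if step == 1:
        return session
    return RecordingSession(
        emg=session.emg[:, ::step, :], fs=session.fs, label=session.label,
        repetition=session.repetition, subject_id=session.subject_id,
        grid=(rows // step, session.grid[1]))


def _segment_runs(label: np.ndarray, repetition: np.ndarray):
    """Contiguous runs of constant (label, repetition), excluding rest."""
    n = len(label)
    if n == 0:
        return
    change = np.flatnonzero((np.diff(label) != 0) | (np.diff(repetition) != 0))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    for s, e in zip(starts, ends):
        if label[s] != REST_LABEL:
            yield int(s), int(e)


def segment_windows(session: RecordingSession, spec: WindowSpec
                    ) -> WindowedDataset:
    """Slide a window of W samples with the given skip step over every
    contiguous (gesture, repetition) segment.

    A segment of length L yields floor((L - W) / skip) + 1 windows starting
    at multiples of the skip; windows never cross a label boundary.
    """
    if (spec.n_ch, spec.n_cv) != session.grid:
        raise ValueError(f"window spec grid ({spec.n_ch}, {spec.n_cv}) does not "
                         f"match session grid {session.grid}")
    windows, labels, reps = [], [], []
    for s, e in _segment_runs(session.label, session.repetition):
        length = e - s
        if length < spec.window:
            continue
        n_win = (length - spec.window) // spec.skip + 1
        for k in range(n_win):
            lo = s + k * spec.skip
            windows.append(session.emg[lo:lo + spec.window])
            labels.append(session.label[s])
            reps.append(session.repetition[s])
    if not windows:
        warnings.warn("no segment is long enough for the requested window size")
        data = np.zeros((0, spec.window, spec.n_ch, spec.n_cv), dtype=np.float32)
        return WindowedDataset(data, np.zeros(0, int), np.zeros(0, int), spec)
    return WindowedDataset(np.stack(windows).astype(np.float32),
                           np.asarray(labels), np.asarray(reps), spec)


def preprocess_session(session: RecordingSession,
                       norm: NormalizationConfig,
                       wspec: WindowSpec,
                       channel_fraction=1,
                       per_channel_scaling: bool = True,
                       apply_mu_law: bool = True) -> WindowedDataset:
    """Run the full fixed-order pipeline and return fold-ready windows."""
    x = rectify(session.emg)
    # float32 from here on: windows are stored in single precision anyway,
    # and this halves the footprint of whole-session intermediates
    x = envelope_filter(x, norm, session.fs, axis=0).astype(np.float32)
    x = scale_to_unit(x, per_channel=per_channel_scaling)
    # the causal filter can overshoot the rectified input's max by a sliver
    np.clip(x, -1.0, 1.0, out=x)
    if apply_mu_law:
        x = mu_law_normalize(x, norm.mu)
    processed = RecordingSession(emg=x, fs=session.fs, label=session.label,
                                 repetition=session.repetition,
                                 subject_id=session.subject_id,
                                 grid=session.grid)
    processed = remove_rest(processed)
    processed = select_channels(processed, channel_fraction)
    return segment_windows(processed, wspec)


def moving_average_window_ms(cutoff_hz: float) -> float:
    """Length of the moving-average window equivalent to a low-pass cutoff.

    A moving-average filter has cutoff f = 0.443 / T_w, so the window
    matching a given cutoff is T_w = 0.443 / f, returned in milliseconds
    (443 ms at 1 Hz).
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff frequency must be positive")
    return 0.443 / cutoff_hz * 1000.0
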