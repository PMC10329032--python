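"""Core in-memory containers shared across the toolkit."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REST_LABEL = 0  # gesture/repetition id reserved for rest samples


@dataclass
class RecordingSession:
    """A labeled multichannel HD-sEMG recording.

    emg        -- (T, rows, cols) signal in volts
    fs         -- sampling rate in Hz
    label      -- per-sample gesture id, 0 = rest
    repetition -- per-sample repetition id, 0 = rest
    """

    emg: np.ndarray
    fs: float
    label: np.ndarray
    repetition: np.ndarray
    subject_id: str = "synthetic"
    grid: tuple[int, int] = (16, 8)

    def __post_init__(self):
        self.emg = np.asarray(self.emg)
        self.label = np.asarray(self.label, dtype=np.int64)
        self.repetition = np.asarray(self.repetition, dtype=np.int64)
        t = self.emg.shape[0]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label.shape[0] != t:
            raise ValueError(
                f"label stream length {self.label.shape[0]} != signal length {t}")
        if self.repetition.shape[0] != t:
            raise ValueError(
                f"repetition stream length {self.repetition.shape[0]} != "
                f"signal length {t}")
        if self.emg.shape[1:] != tuple(self.grid):
            raise ValueError(
                f"signal grid {self.emg.shape[1:]} != declared grid {self.grid}")
        self.grid = tuple(self.grid)

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class WindowSpec:
    """Sliding-window segmentation parameters.

    window -- W, samples per window
    skip   -- hop between window starts, samples
    n_ch   -- horizontal channels kept (grid rows), n_cv -- vertical (columns)
    """

    window: int
    skip: int
    n_ch: int = 16
    n_cv: int = 8

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window size must be >= 1")
        if self.skip < 1:
            raise ValueError("skip step must be >= 1")


@dataclass
class WindowedDataset:
    """Segmented 3-D windows with gesture / repetition labels."""

    windows: np.ndarray          # (n, W, n_ch, n_cv)
    labels: np.ndarray           # (n,)
    repetitions: np.ndarray      # (n,)
    spec: WindowSpec

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetitions = np.asarray(self.repetitions, dtype=np.int64)
        n = self.windows.shape[0]
        if self.labels.shape[0] != n or self.repetitions.shape[0] != n:
            raise ValueError("windows / labels / repetitions length mismatch")

    def __len__(self) -> int:
        return self.windows.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(self.windows[mask], self.labels[mask],
                               self.repetitions[mask], self.spec)
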