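"""Synthetic HD-sEMG generator.

Sessions are built as convolutive mixtures of motor-unit action potentials
(MUAPs): every motor unit (MU) owns a temporal template and a Gaussian
spatial profile over the electrode grid, fires according to a Gaussian-ISI
renewal process whose rate is gated per gesture by an activation matrix, and
contributes the spatially weighted template at every firing instant.  Rest
intervals separate gesture repetitions and contain measurement noise only.
The full ground truth (spike trains, per-channel templates, labels) is
emitted alongside the signal so that decomposition, spike-triggered
averaging and the classifiers can all be validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import REST_LABEL, RecordingSession


def biphasic_template(length: int = 15, width: float = 2.0,
                      amplitude: float = 1.0) -> np.ndarray:
    """Default MUAP shape: first derivative of a Gaussian (biphasic),
    peak-normalized to ``amplitude``.  Fits inside the 20-sample STA window.
    """
    t = np.arange(length) - (length - 1) / 2.0
    x = -t * np.exp(-t ** 2 / (2.0 * width ** 2))
    return amplitude * x / np.abs(x).max()


@dataclass
class MotorUnitSpec:
    """One motor unit: where it sits on the grid, how it looks, how it fires."""

    territory_center: tuple[float, float]   # (row, col) on the grid
    spatial_spread: float                   # std of the Gaussian profile, electrodes
    temporal_template: np.ndarray           # <= 20 samples, unitless amplitude
    mean_rate: float                        # firings / second
    isi_cov: float = 0.2                    # coefficient of variation of the ISI

    def __post_init__(self):
        self.temporal_template = np.asarray(self.temporal_template, dtype=float)
        if self.temporal_template.ndim != 1 or len(self.temporal_template) > 20:
            raise ValueError("temporal template must be 1-D with length <= 20")
        if self.mean_rate <= 0:
            raise ValueError("mean firing rate must be positive")
        if self.spatial_spread <= 0:
            raise ValueError("spatial spread must be positive")

    def spatial_weights(self, grid: tuple[int, int]) -> np.ndarray:
        """exp(-dist^2 / 2 sigma^2) over the grid, Euclidean electrode distance."""
        rows, cols = grid
        r0, c0 = self.territory_center
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        return np.exp(-d2 / (2.0 * self.spatial_spread ** 2))


@dataclass
class SyntheticSessionSpec:
    """Layout and physiology of one synthetic recording session."""

    n_gestures: int
    motor_units: list[MotorUnitSpec]
    activation: np.ndarray                 # (n_gestures, n_mu) in [0, 1]
    repetition_duration: float = 5.0       # seconds of active signal
    rest_duration: float = 5.0             # seconds of rest between repetitions
    n_repetitions: int = 5
    noise_std: float = 0.05                # volts
    grid: tuple[int, int] = (16, 8)
    fs: float = 2048.0
    seed: int = 0
    # inter-repetition variability: territory displacement (std, electrode
    # units; electrode re-positioning / posture scale) and firing-rate
    # modulation (uniform in 1 +- rep_rate_jitter; effort / fatigue scale)
    rep_jitter: float = 0.3
    rep_rate_jitter: float = 0.15

    def __post_init__(self):
        self.activation = np.asarray(self.activation, dtype=float)
        if not self.motor_units:
            raise ValueError("at least one motor unit is required")
        if self.repetition_duration <= 0 or self.rest_duration < 0:
            raise ValueError("durations must be positive (rest may be zero)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.activation.shape != (self.n_gestures, len(self.motor_units)):
            raise ValueError(
                f"activation must be (n_gestures, n_mu) = "
                f"({self.n_gestures}, {len(self.motor_units)})")
        if self.activation.min() < 0 or self.activation.max() > 1:
            raise ValueError("activation entries must lie in [0, 1]")
        if self.rep_jitter < 0 or self.rep_rate_jitter < 0:
            raise ValueError("repetition jitter parameters must be >= 0")
        if np.any(self.activation.sum(axis=1) == 0):
            raise ValueError("every gesture must activate at least one MU")
        self.grid = tuple(self.grid)


@dataclass
class GroundTruth:
    """Everything the generator knows that a decomposition must rediscover."""

    spike_trains: dict          # (gesture, repetition, mu) -> sorted sample indices
    templates: np.ndarray       # (n_mu, rows, cols, max_template_len) per-channel
                                # MUAPs at the nominal (unjittered) territory
    temporal_templates: np.ndarray  # (n_mu, max_template_len) temporal part
    weights: dict               # (gesture, repetition, mu) -> (rows, cols) spatial
                                # profile actually used in that repetition
    template_offsets: np.ndarray  # per-MU placement offset relative to spike index
    template_lengths: np.ndarray  # per-MU true template support (rest is zero padding)
    labels: np.ndarray          # per-sample gesture id (0 = rest)
    repetitions: np.ndarray     # per-sample repetition id (0 = rest)

    def spikes_for_mu(self, mu: int) -> np.ndarray:
        idx = [v for (g, r, m), v in self.spike_trains.items() if m == mu]
        return np.sort(np.concatenate(idx)) if idx else np.array([], dtype=int)

    def _contrib(self, g: int, r: int, m: int) -> np.ndarray:
        """(L, rows, cols) waveform one firing of MU m adds in (g, r)."""
        length = int(self.template_lengths[m])
        temporal = self.temporal_templates[m, :length]
        return temporal[:, None, None] * self.weights[(g, r, m)][None, :, :]

    def reconstruct_mu(self, mu: int, n_samples: int) -> np.ndarray:
        """Noise-free contribution of one MU to the whole session."""
        rows, cols = self.templates.shape[1:3]
        length = int(self.template_lengths[mu])
        off = int(self.template_offsets[mu])
        out = np.zeros((n_samples, rows, cols))
        for (g, r, m), spikes in self.spike_trains.items():
            if m != mu:
                continue
            contrib = self._contrib(g, r, m)
            for t in spikes:
                out[t - off:t - off + length] += contrib
        return out

    def reconstruct(self, n_samples: int, dtype=np.float32) -> np.ndarray:
        """Noise-free superposition of all MU contributions.

        Replays the generator's accumulation order and dtype, so with zero
        noise the result is bit-identical to the emitted signal.
        """
        rows, cols = self.templates.shape[1:3]
        out = np.zeros((n_samples, rows, cols), dtype=dtype)
        for (g, r, m), spikes in self.spike_trains.items():
            length = int(self.template_lengths[m])
            off = int(self.template_offsets[m])
            contrib = self._contrib(g, r, m)
            for t in spikes:
                out[t - off:t - off + length] += contrib
        return out


def _segment_layout(spec: SyntheticSessionSpec):
    """Gesture-major timeline: each active repetition followed by a rest gap."""
    fs = spec.fs
    rep_len = int(round(spec.repetition_duration * fs))
    rest_len = int(round(spec.rest_duration * fs))
    segments = []  # (gesture 1-based, repetition 1-based, start, end)
    cursor = 0
    for g in range(1, spec.n_gestures + 1):
        for r in range(1, spec.n_repetitions + 1):
            segments.append((g, r, cursor, cursor + rep_len))
            cursor += rep_len + rest_len
    total = cursor
    return segments, total


def _renewal_train(rng: np.random.Generator, rate: float, fs: float,
                   lo: int, hi: int, isi_cov: float) -> np.ndarray:
    """Gaussian-ISI renewal process on sample indices in [lo, hi)."""
    if rate <= 0 or hi <= lo:
        return np.array([], dtype=int)
    mean_isi = fs / rate
    t = lo + rng.uniform(0.0, mean_isi)
    spikes = []
    while t < hi:
        spikes.append(int(round(t)))
        isi = rng.normal(mean_isi, isi_cov * mean_isi)
        t += max(isi, 1.0)
    return np.array([s for s in spikes if lo <= s < hi], dtype=int)


def generate_session(spec: SyntheticSessionSpec
                     ) -> tuple[RecordingSession, GroundTruth]:
    """Render a session from its spec.  Identical seeds give identical output.

    Per channel c the signal is sum over MUs m and firings t_k of
    ``template_m * w_{m,c}`` placed around t_k, plus white Gaussian noise;
    ``w_{m,c}`` is the MU's Gaussian spatial profile evaluated at c.
    """
    rng = np.random.default_rng(spec.seed)
    segments, total = _segment_layout(spec)
    rows, cols = spec.grid
    emg = np.zeros((total, rows, cols), dtype=np.float32)
    label = np.full(total, REST_LABEL, dtype=np.int64)
    repetition = np.full(total, REST_LABEL, dtype=np.int64)

    n_mu = len(spec.motor_units)
    max_len = max(len(mu.temporal_template) for mu in spec.motor_units)
    templates = np.zeros((n_mu, rows, cols, max_len))
    temporal = np.zeros((n_mu, max_len))
    offsets = np.zeros(n_mu, dtype=int)
    lengths = np.zeros(n_mu, dtype=int)
    for m, mu in enumerate(spec.motor_units):
        w = mu.spatial_weights(spec.grid)
        L = len(mu.temporal_template)
        templates[m, :, :, :L] = w[:, :, None] * mu.temporal_template[None, None, :]
        temporal[m, :L] = mu.temporal_template
        offsets[m] = L // 2
        lengths[m] = L

    spike_trains: dict = {}
    rep_weights: dict = {}
    for g, r, start, end in segments:
        label[start:end] = g
        repetition[start:end] = r
        for m, mu in enumerate(spec.motor_units):
            # per-repetition variability: territory displacement and rate
            # modulation (drawn for every (segment, MU) to keep the random
            # stream independent of the activation pattern)
            jitter = rng.normal(0.0, spec.rep_jitter or 0.0, size=2) \
                if spec.rep_jitter > 0 else np.zeros(2)
            rate_factor = rng.uniform(1.0 - spec.rep_rate_jitter,
                                      1.0 + spec.rep_rate_jitter) \
                if spec.rep_rate_jitter > 0 else 1.0
            rate = mu.mean_rate * rate_factor * spec.activation[g - 1, m]
            if rate <= 0:
                continue
            L = len(mu.temporal_template)
            off = offsets[m]
            # keep the full template inside the active segment
            spikes = _renewal_train(rng, rate, spec.fs,
                                    start + off, end - (L - off) + 1, mu.isi_cov)
            if spikes.size == 0:
                continue
            shifted = MotorUnitSpec(
                territory_center=(mu.territory_center[0] + jitter[0],
                                  mu.territory_center[1] + jitter[1]),
                spatial_spread=mu.spatial_spread,
                temporal_template=mu.temporal_template,
                mean_rate=mu.mean_rate, isi_cov=mu.isi_cov)
            w = shifted.spatial_weights(spec.grid)
            spike_trains[(g, r, m)] = spikes
            rep_weights[(g, r, m)] = w
            contrib = mu.temporal_template[:, None, None] * w[None, :, :]
            for t in spikes:
                emg[t - off:t - off + L] += contrib

    if spec.noise_std > 0:
        chunk = 1 << 18
        for lo in range(0, total, chunk):
            hi = min(lo + chunk, total)
            emg[lo:hi] += rng.normal(0.0, spec.noise_std,
                                     size=(hi - lo, rows, cols))

    session = RecordingSession(emg=emg, fs=spec.fs, label=label,
                               repetition=repetition, grid=spec.grid)
    truth = GroundTruth(spike_trains=spike_trains, templates=templates,
                        temporal_templates=temporal, weights=rep_weights,
                        template_offsets=offsets, template_lengths=lengths,
                        labels=label, repetitions=repetition)
    return session, truth


def make_separable_benchmark(n_gestures: int, difficulty: float, seed: int,
                             mu_per_gesture: int = 3,
                             repetition_duration: float = 8.0,
                             rest_duration: float = 5.0,
                             n_repetitions: int = 5,
                             grid: tuple[int, int] = (16, 8),
                             fs: float = 2048.0,
                             noise_std: float = 0.05,
                             matched_power: bool = False
                             ) -> SyntheticSessionSpec:
    """A benchmark spec whose class separability is controlled by ``difficulty``.

    Each gesture owns ``mu_per_gesture`` motor units.  At difficulty 0 the
    per-gesture activation rows select disjoint MU subsets; at difficulty 1
    all rows are identical (every gesture drives every MU equally); values
    in between interpolate linearly.

    With ``matched_power`` every MU shares the same template, firing rate and
    spatial spread, so gestures differ only in where their MUs sit on the
    grid -- the regime in which the motor-unit (micro) pathway carries the
    discriminative information.
    """
    if n_gestures < 2:
        raise ValueError("need at least 2 gestures")
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = grid
    n_mu = n_gestures * mu_per_gesture

    # spread territory centers over the grid, seeded jitter
    motor_units = []
    for m in range(n_mu):
        center = (rng.uniform(1.0, rows - 2.0), rng.uniform(1.0, cols - 2.0))
        if matched_power:
            template = biphasic_template(15, width=2.0, amplitude=1.0)
            rate, spread = 20.0, 1.5
        else:
            template = biphasic_template(
                15, width=rng.uniform(1.5, 3.0), amplitude=rng.uniform(0.8, 1.2))
            rate = rng.uniform(15.0, 25.0)
            spread = rng.uniform(1.0, 2.0)
        motor_units.append(MotorUnitSpec(
            territory_center=center, spatial_spread=spread,
            temporal_template=template, mean_rate=rate, isi_cov=0.2))

    block = np.zeros((n_gestures, n_mu))
    for g in range(n_gestures):
        block[g, g * mu_per_gesture:(g + 1) * mu_per_gesture] = 1.0
    activation = (1.0 - difficulty) * block + difficulty * np.ones_like(block)

    return SyntheticSessionSpec(
        n_gestures=n_gestures, motor_units=motor_units, activation=activation,
        repetition_duration=repetition_duration, rest_duration=rest_duration,
        n_repetitions=n_repetitions, noise_std=noise_std, grid=grid, fs=fs,
        seed=int(rng.integers(0, 2 ** 31 - 1)))
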