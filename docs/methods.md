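# Methods

This note records the models implemented in `hdsemg`, the assumptions and
parameter choices behind them, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want to know.

## Signal model and generator

HD-sEMG is modelled as a convolutive mixture: each motor unit (MU) m owns a
temporal MUAP template u_m(t) and a spatial profile
w_{m,c} = exp(−‖c − c_m‖² / 2σ_m²) over the electrode grid (Euclidean
distance in electrode units, matching a uniform grid), and the signal at
channel c is

    x_c(t) = Σ_m Σ_k  u_m(t − t_{mk}) · w_{m,c}  +  ε_c(t),

with firing times t_{mk} drawn from a Gaussian-ISI renewal process (ISI
mean fs/rate, ISI std = CoV × mean, truncated at one sample) and white
Gaussian noise ε.  Per gesture, MU firing rates are gated by an activation
matrix with entries in [0, 1]; rest intervals contain noise only.  Sessions
follow the protocol of the target application: each gesture performed 5
times with rest in between, at 2,048 Hz on a 16×8 grid (both configurable).

Defaults: biphasic template (first derivative of a Gaussian, 15 samples,
peak-normalized) — the shape fits inside the 20-sample spike-triggered
averaging window; ISI CoV 0.2 and rates of 15–25 Hz, typical for moderate
voluntary contractions; noise_std 0.05 on unit-amplitude templates.  The
template is placed centered on the reported spike index, and firings are
kept far enough from segment edges that the full template lies inside its
repetition — so rest is exactly silent and spike-triggered averages are
unclipped.

Repetitions of the same gesture are not statistically identical, and this
matters: the well-known optimism of shuffled train/test splits over
repetition-wise cross-validation only exists if repetitions vary.  The
generator therefore draws, per (repetition, MU), a small displacement of
the MU territory (Gaussian, std `rep_jitter` = 0.3 electrode units ≈ 3 mm
on a 10 mm grid — the scale of electrode re-positioning and posture
shifts) and a firing-rate modulation factor (uniform in 1 ± 0.15, the
scale of effort/fatigue drift).  Both default values were fixed once on
these physiological grounds; setting them to 0 recovers exchangeable
repetitions.  The ground truth stores the per-(gesture, repetition, MU)
spatial profile actually used, so the noise-free superposition replay
remains bit-exact.

The `make_separable_benchmark` helper builds class structure with one knob:
at difficulty 0 each gesture drives a disjoint MU subset; at difficulty 1
all gestures share identical activation rows (chance-level task); values in
between interpolate linearly.  `matched_power=True` gives every MU the same
template, rate and spread so gestures differ only in where their MUs sit —
the regime in which the motor-unit image pathway carries the class
information.

What the generator does **not** emulate: volume-conductor filtering and
electrode-skin impedance variation, force-dependent recruitment and rate
coding, MUAP shape nonstationarity, motion artifacts, power-line
interference, inter-subject variability.  Passing tests therefore
demonstrate that each algorithm recovers what it is designed to recover
under its own generative assumptions — not that real-electrode accuracy
figures transfer.

## Preprocessing

Fixed order: full-wave rectification → first-order Butterworth low-pass
(default 1 Hz; 5 and 10 Hz supported) applied causally per channel (a
zero-phase forward-backward variant is available by flag) → amplitude
scaling → μ-law companding (μ = 255 by default) → rest removal → channel
subsetting → windowing.  Rectification before filtering is essential: the
low-pass of a zero-mean signal is near zero, the low-pass of its absolute
value is the linear envelope (a property asserted by test).  A first-order
low-pass at cutoff f behaves like a moving average of length
T_w = 0.443 / f (443 ms at 1 Hz), which `moving_average_window_ms` exposes.

μ-law companding is only a [−1,1] → [−1,1] map, so envelopes are first
divided by their per-channel maximum absolute value (a global-maximum mode
is available).  The reference for that maximum is the whole session by
default: fold splits are defined after windowing, so a per-fold maximum is
not available at this stage; a sample mask can restrict the reference when
a strict train-only scaling is wanted.

Channel subsetting decimates the 16-row stacked-grid axis (every 2nd or 4th
row), keeping the 8 columns — coverage of the recorded area is preserved
while the inter-electrode distance grows.  Windowing slides a W-sample
window with a skip step inside each contiguous (gesture, repetition) run;
windows never straddle label boundaries.  All indices are 0-based and
windows are half-open [start, start + W).

## Transformer

Patch embedding uses non-overlapping H × V × N_cv tiles (time-major order,
flattened time → horizontal → vertical), a bias-free linear projection, a
learnable class token, and a learnable 1-D positional embedding of shape
(N+1) × d.  Encoder layers are pre-norm residual blocks; MSA splits d into
h heads and scales by √(d/h) (the literal pre-split √d is available via
`attention_scale="full-d"`); the MLP uses GELU.  The head is a single
linear layer on the final class-token row.  There is no dropout, no final
layer norm, and no projection bias: this exact tensor inventory is what
makes the closed-form parameter count land on the published totals
bit-exactly, which the tests assert for every standard configuration.

Initialization is truncated normal (std 0.02, clipped at 2σ) for
embeddings and projections, zeros for biases, ones/zeros for norm scales
and shifts, all from a seeded generator; forward passes are deterministic
given parameters.

Training follows the stated recipe: Adam (β₁ 0.9, β₂ 0.999), learning rate
1e-4, weight decay 1e-3 (L2-coupled), cross-entropy, 20 epochs at batch
size 128, learning rate constant for the first 10 epochs then annealed —
linear decay to zero is the default, cosine available.  Runs shorter than
the annealing onset simply never anneal.  Weight decay applies to all
parameters (norms and embeddings included); this and the annealing shape
were genuinely open choices and are configurable.

The networks run on `hdsemg.nn`, a compact tape-based reverse-mode autodiff
core over numpy arrays written for this package, with Adam and the usual
layers (linear, layer norm, multi-head attention, valid 3-D convolution,
max pooling, dropout).  Its gradients are verified against central finite
differences down to ~1e-10 absolute error.  Arithmetic defaults to float64;
a `using_dtype(np.float32)` context roughly halves training time and is
used for the long benchmark runs.

## Evaluation

By-repetition cross-validation holds each repetition out once (5 folds);
the shuffled protocol pools windows across repetitions before splitting and
is optimistic, because windows overlapping the test repetitions' signal
appear in training — the suite asserts the direction of that gap.
Confusion counts are summed over folds and row-normalized; per-class
precision, recall and F1 come from the count matrix, and the multiclass
MCC uses the generalized (R_k) formulation.  Zero-denominator classes
report 0 and are flagged.  Wilcoxon signed-rank comparisons annotate
p-values with the conventional ns/*/**/***/**** bins.  Positional-embedding
similarity matrices use cosines of the patch rows only (the class-token row
is excluded; its position is structural, not temporal).

## Motor-unit decomposition

The blind-source-separation stage follows the standard EMG decomposition
contract: delay-embed each channel with R delayed copies (R = 10 by
default), center, whiten by eigendecomposition (directions below 1e-8 of
the top eigenvalue are dropped — essential for noise-free mixtures whose
extended covariance is rank-deficient), then estimate up to `max_sources`
(default 7) separation vectors by deflationary fixed-point ICA.  The
contrast is skewness by default: MU spike trains are sparse and positively
skewed after projection, and in high-dimensional whitened spaces the
kurtosis contrast reliably collapses onto single-sample directions, which
skewness does not.  Each new-source attempt is seeded with the
highest-energy still-unused whitened column (an actual activity burst)
rather than a random vector, and after convergence the vector is refined a
few times as the mean of the whitened columns at the detected firing
instants — a spike-triggered update that only survives for repeatable
sources and is what rejects pure-noise inputs.

Spikes are detected by peak picking on the squared source (minimum
inter-peak distance 10 samples ≈ 5 ms) followed by a two-means split of
peak heights; the source is accepted iff the silhouette of that split
clears the threshold (0.92 by default, interpreted on the raw [−1, 1]
silhouette scale), it fired at least `min_spikes` times (default 4), and it
is not a duplicate of an earlier source (> 50% best-lag overlap at ±1
sample — blind sources are recovered at arbitrary delays inside the
extension range, so duplicate detection must search over lags).  Because
the attempt trajectory does not depend on the threshold, raising the
threshold can only shrink the accepted set (asserted by test).  Merged
sources (one vector capturing two units) occasionally pass the gate on
dense mixtures; they lower the mean spike-train F1 but are bounded by the
duplicate check, and the recovery criterion (mean F1 ≥ 0.9 at ±1 sample on
≤ 5-unit mixtures at ≥ 20 dB) holds with margin.

Short windows are a special regime: with T comparable to the extended
dimension M, exact whitening equalizes the signal and noise subspaces and
destroys the matched-filter structure.  `whiten_shrinkage` blends the
sample covariance toward the sphere (tr(C)/M·I) before inversion; the
fusion pipeline decomposes 512-sample (250 ms) windows with shrinkage 0.5,
extension 2 and `min_spikes` 2 (a 15–25 Hz unit fires only 3–6 times in
250 ms).

Spike-triggered averaging uses a 20-sample window centered on the spike
index; boundary-clipped segments are dropped and duplicate indices count
once.  Because sources carry an unknown delay, the raw-window alignment for
each source is chosen (among the R+1 extension offsets) to maximize the
template energy.  Per-channel max − min of the templates gives the
N_ch × N_cv peak-to-peak MUAP image; it is invariant to per-channel DC
offsets.

## Fusion

The macro path (V1 on 512-sample windows, skip 256) and the micro path
(V3: d = 64 on the peak-to-peak image fed as an n_cv-sample × n_ch-channel
single-channel window, patch (8,8) — two patches on the full 16×8 grid)
are trained independently; the micro path treats every MU image as its own
training sample (Adam, lr 3e-4, weight decay 1e-3, batch 64, 50 epochs).
Both backbones are then frozen and their heads bypassed: per window, the
macro class token and the mean of the available micro class tokens
(max-pooling available; a zero vector with a flag when no MU was accepted)
are concatenated (2d = 128), expanded by one linear layer + GELU to 1,024
features, and classified by a final linear layer.  How the concatenated
vector maps to 1,024 dimensions and how many FC layers follow was not
uniquely specified; one expansion layer plus one output layer is the
default and the widths are configurable.  Fusion training computes both
tokens with gradients detached and hands only the fusion head to the
optimizer, so backbone tensors are untouched by construction (asserted
bit-exactly by test).

## Baselines

TD-PSD features per channel: m_k = root^λ/λ with λ = 0.1 (the canonical
value in the feature family's source literature; configurable), where the
roots are RMS values of forward differences with the divisor kept at the
original length N.  The default `as-printed` mode keeps the formulation in
which the second- and third-moment roots coincide, making the m₃ − m₂
feature identically zero — an algebraic property of that formulation which
the tests pin down; the `ordered` mode maps the five roots onto difference
orders 0–4 and removes the degeneracy.  The classical set is RMS, strict
zero crossings, strict slope-sign changes and waveform length.  Both sets
feed an RBF-SVM or LDA, standardized per training fold, evaluated with
exactly the same by-repetition folds as the deep models; singular LDA
covariances fall back to shrinkage estimation.  The 3-D CNN baseline uses
two valid stride-1 conv blocks (16 and 32 filters of (5,3,3), GELU,
dropout 0.2, time-axis max pooling) and 256/128 FC layers; pooling extents
and padding were not uniquely specified, so its total parameter count is
not treated as a checkable quantity (the conv-layer counts, 736 and
23,072, are).

## Problem sizes used in the test suite

The suite runs entirely on synthetic data at desk scale, chosen so the full
run finishes in well under half an hour on one CPU core:

- end-to-end classification: 8 gestures × 5 repetitions × 8 s active
  (40 s per gesture), 64 of 128 channels, W = 64, skip 32 (≈ 20,000
  windows), full 5-fold by-repetition CV with the stated hyperparameters;
- decomposition recovery: 5 units on an 8×8 grid, 10 s, ≈ 20 dB SNR;
- fusion: 4 gestures × 5 × 2 s on an 8×8 grid, W = 512, skip 256, five
  generator seeds, one held-out repetition per seed;
- protocol comparison: 4 gestures at difficulty 0.6, W = 64, skip 32.

## Known limitations

- Decomposition is offline and per-window; units are not tracked across
  windows, and merged sources can survive the silhouette gate on dense
  mixtures.
- The silhouette threshold 0.92 is interpreted on the raw [−1, 1] scale of
  the standard per-point silhouette; other decomposition codebases define
  the measure differently, so the numeric threshold need not transfer.
- The μ-law pre-scaling convention (per-channel max over the session) is a
  documented choice; alternatives change absolute envelope levels but not
  the companding map's properties.
- The autodiff core favors clarity over throughput; it is adequate for the
  ~10⁵-parameter models here, not for large-scale training.
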