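# hdsemg — transformer-based gesture recognition for high-density surface EMG

`hdsemg` is a toolkit for hand-gesture classification from high-density
surface electromyography (HD-sEMG): muscle activity recorded at 2,048 Hz on a
16×8 electrode grid.  It implements, end to end and on CPU:

- **A compact vision transformer** for windowed HD-sEMG.  A window of shape
  W × N_ch × N_cv is tiled into N = W·N_ch/(H·V) patches, each flattened and
  linearly projected (no bias) into a d-dimensional embedding; a learnable
  class token is prepended, a learnable (N+1)×d positional embedding added,
  and L pre-norm encoder layers with h-head self-attention
  (softmax(QKᵀ/√d_head)·V) process the sequence:

      z′_l = MSA(LN(z_{l−1})) + z_{l−1},   z_l = MLP(LN(z′_l)) + z′_l

  The classification head is one linear layer reading only the class-token
  row.  Two standard sizes are built in (V1: d=64, L=1, h=8; V2: d=128,
  m=256) plus an image variant (V3) and a single-frame "instantaneous" mode.
  A closed-form parameter counter matches the framework's trainable-tensor
  count bit-exactly (e.g. 46,530 parameters for V1 at 32 channels, W=64).
- **The preprocessing chain**: full-wave rectification → first-order
  Butterworth low-pass envelope (1/5/10 Hz) → per-channel scaling →
  μ-law companding F(x) = sign(x)·ln(1+μ|x|)/ln(1+μ) → rest removal →
  channel subsetting (128/64/32) → sliding-window segmentation.
- **Motor-unit decomposition** (the "micro" pathway): delay-embedded
  whitening plus deflationary fixed-point ICA with a skewness contrast
  extracts up to 7 motor-unit spike trains per window, each gated by the
  silhouette (≥ 0.92) of a two-means split of its peak amplitudes;
  spike-triggered averaging (20-sample window) and per-channel peak-to-peak
  values turn each unit into an N_ch × N_cv MUAP image.
- **A frozen-backbone fusion model** that concatenates the macro (windowed
  signal) and micro (MUAP image) class tokens, expands them to a
  1,024-dimensional feature vector and classifies through fully connected
  layers.
- **Baselines**: TD-PSD spectral-moment features (m₀…m₄ via Parseval's
  theorem and discrete derivatives) and the classical RMS/ZC/SSC/WL set
  feeding SVM/LDA, plus a small 3-D CNN.
- **A synthetic HD-sEMG generator** producing sessions as convolutive
  mixtures of motor-unit action potentials driven by Gaussian-ISI renewal
  spike trains, with gesture × repetition × rest structure and complete
  ground truth — so every stage is testable without any external dataset.

All networks run on a small numpy reverse-mode autodiff core bundled in
`hdsemg.nn` (verified against finite differences); evaluation follows
by-repetition 5-fold cross-validation with per-class precision/recall/F1,
generalized multiclass MCC, row-normalized confusion matrices and Wilcoxon
signed-rank comparisons.

## Worked example

```python
import numpy as np
from hdsemg.synth import make_separable_benchmark, generate_session
from hdsemg.preprocess import NormalizationConfig, WindowSpec, preprocess_session
from hdsemg.train_eval import TrainConfig, crossval_by_repetition
from hdsemg.vit import standard_configs
from hdsemg.nn import using_dtype

spec = make_separable_benchmark(n_gestures=4, difficulty=0.0, seed=1,
                                repetition_duration=3.0, rest_duration=2.0)
session, truth = generate_session(spec)
dataset = preprocess_session(session, NormalizationConfig(),
                             WindowSpec(64, 32, 8, 8), channel_fraction=0.5)
config = standard_configs("V1", window=64, channels=64, n_classes=4)
with using_dtype(np.float32):
    report = crossval_by_repetition(dataset, config, TrainConfig(seed=0))
print([round(a, 1) for a in report.fold_accuracies], round(report.mean_accuracy, 2))
```

prints

```
[99.6, 99.7, 99.3, 99.7, 99.7] 99.63
```

— the five per-fold accuracies (each repetition held out once) and their
mean, in percent.  Four gestures driven by disjoint motor-unit subsets are
almost perfectly separable from the 64-channel envelope pattern; raising
`difficulty` toward 1 makes the activation rows overlap and the accuracy
fall toward chance.

A thin CLI wraps the same functions:

```bash
hdsemg simulate --out data/ --n-gestures 8 --seed 1
hdsemg preprocess --in data/session.h5 --out data/win.h5 --window 64 --channels half
hdsemg train --windows data/win.h5 --variant V1
hdsemg describe --variant V1 --window 64 --channels 32   # parameter breakdown
```

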