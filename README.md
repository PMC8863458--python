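# eegfusion

Few-shot epileptic-seizure detection from single-channel EEG by **hybrid-input
fusion**: each EEG segment is presented to the classifier simultaneously as
its raw time series, its DFT magnitude spectrum, a Hamming-window STFT
spectrogram, and a two-level db1 (Haar) DWT coefficient vector.  Four
lightweight CNN branches — one per representation, built from
depthwise-separable convolutions to stay small (≈ 17 k parameters total) —
each emit a 32-dimensional feature; the concatenated 128-dimensional feature
`F = F₁ ⊕ F₂ ⊕ F₃ ⊕ F₄` is classified by a softmax head.

The target regime is *few-shot*: evaluation uses inverted N-fold
cross-validation, where each class-stratified fold (10–40 samples) is the
training set and the remaining N−1 folds are the validation set.  Reported
per-method statistics are the mean of per-fold accuracies and their sample
standard deviation.

The package is for researchers studying EEG seizure-detection pipelines:
it ships the transforms, the model, the training loop (Adam, batch 6,
lr 0.005 halved every 20 epochs, l2 λ = 1e-4), the protocol, a reader for
the standard five-set plain-text EEG layout (sets A–E, 100 × 4097-sample
segments), and a synthetic EEG generator so everything is testable without
the clinical recordings.  There is no deep-learning-framework dependency —
the CNN engine (im2col/GEMM convolutions, manual backprop) is pure numpy.

## Worked example

```python
from eegfusion import (SeizureClassifier, SynthConfig, TrainConfig,
                       generate_dataset, run_experiment)

segments = generate_dataset(SynthConfig(n_per_class=10, length=1024, seed=7))
model = SeizureClassifier.from_segments(
    segments, method="Hybrid", train_config=TrainConfig(max_epochs=20, seed=0))
results = model.fit()
print(results.summary())
```

```
Hybrid seizure classifier fit
==============================================
method:            Hybrid
branches:          raw, dft, stft, dwt
fused feature dim: 128
parameters:        16866
  raw              3856
  dft              3856
  stft             5040
  dwt              3856
  head             258
samples:           20
epochs:            20 (batch 6, lr0 0.005, halved every 20)
l2 lambda:         0.0001
final loss:        0.1754
final train acc:   1.0000
```

The fit summary shows the four branches, the 128-dimensional fused feature,
the per-component parameter counts, and the final regularized cross-entropy
and training accuracy.  Cross-validated comparison under the inverted
protocol (here 5 folds over 20 segments, so each fold trains on just 4):

```python
report = run_experiment(segments, method="Hybrid", n_folds=5,
                        train_config=TrainConfig(max_epochs=20), seed=3)
print(report.summary().to_string())
```

```
          K1      K2      K3   K4      K5    Mean  Variance
Hybrid  0.75  0.9375  0.9375  1.0  0.6875  0.8625    0.1355
```

K1–K5 are per-fold validation accuracies; `Mean` is their average and
`Variance` their sample standard deviation — large here because four
training samples per fold is an extreme few-shot setting; with 20 training
samples the hybrid model reaches ≈ 0.99 on the synthetic contrast.  (On this
generator the DFT-only baseline is nearly perfect by construction — the two
classes occupy disjoint frequency bands — so, unlike on real recordings,
fusion cannot strictly dominate it; `docs/methods.md` discusses this.)

A CLI mirrors the library (`eegfusion simulate / transform / train /
evaluate / report / summary`):

```bash
eegfusion simulate --n 100 --seed 7 --out data/
eegfusion evaluate --data data/ --folds 10 --epochs 30 --seed 42 --out table.csv
eegfusion summary --method Hybrid
```

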