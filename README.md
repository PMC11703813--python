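# bruitnet

Classification of arteriovenous-fistula (AVF) shunt sounds.

A hemodialysis fistula produces an audible turbulence sound (a *bruit*)
whose character changes when the vessel narrows: healthy fistulas carry
relatively uniform broadband energy, while stenotic ones sound weaker, with
energy scattered into intermittent narrowband components. `bruitnet`
implements an auscultation-to-label pipeline for 24–30 s, 16 kHz stethoscope
recordings labelled *normal* / *abnormal* (stenotic, fistula diameter
< 1.8 mm):

1. **Augmentation** — additive white noise at a configurable SNR and random
   clipping into 3–6 s and 18–21 s segments rebalance a 600:200
   normal:abnormal corpus into 1,200 recordings per class, split 70/10/20
   into train/validation/test.
2. **Feature fusion** — pre-emphasis `y[n] = x[n] − 0.97·x[n−1]`, a
   128-band log-mel spectrogram (25 ms Hann window, 10 ms hop) resized to
   128 frames, 13 MFCCs per frame, per-frame min–max normalization of both,
   row-wise concatenation into a (141, 128) matrix, renormalization, and
   reshaping to the (time = 128, feature = 141, channel = 1) model input.
3. **CBAM-LSTM classifier** — three convolutional blocks
   (3×3 conv → LeakyReLU → BatchNorm → CBAM → 2×2 max-pool → dropout, with
   64/128/256 filters), where CBAM applies channel attention
   `F₁ = M_c(F) ⊙ F` followed by spatial attention `F₂ = M_s(F₁) ⊙ F₁`,
   then an LSTM over the 16 pooled time steps and a sigmoid output unit.
   Training minimizes binary cross-entropy with Adam (lr 0.001, batch 64,
   ≤ 300 epochs, early stopping on validation loss).
4. **Evaluation** — confusion counts with precision / recall / F1 /
   accuracy, ROC/AUROC, and a PSNR/SSIM procedure that quantifies how
   strongly each feature type (mel, MFCC, fused) separates the two classes.

Clinical recordings of this kind are not publicly deposited, so the package
ships a seeded synthetic bruit generator (`bruitnet.bruit_synth`) that
reproduces the qualitative class contrast, making every stage testable end
to end. The neural network runs on a compact numpy reverse-mode autodiff
core (`bruitnet.nn`) — no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from bruitnet.bruit_synth import BruitParams, generate_dataset
from bruitnet.features import featurize_many
from bruitnet.model import ModelConfig, build_model, train, predict
from bruitnet.metrics import evaluate

recs, manifest = generate_dataset(40, 40, BruitParams(separation=0.8), seed=11)
x, y, ids = featurize_many(recs)
print(x.shape)                       # (80, 128, 141, 1)

order = np.random.default_rng(0).permutation(len(y))  # mix the classes
x, y = x[order], y[order]
cfg = ModelConfig(conv_filters=(8, 16, 32), cbam_reduction=4, lstm_units=32,
                  dense_units=32, batch_size=32, dropout_rate=0.2,
                  learning_rate=0.002, max_epochs=12, seed=0)
net = build_model(cfg)
trace = train(net, x[:48], y[:48], x[48:64], y[48:64])
_, probs = predict(net, x[64:])
report = evaluate(y[64:], probs)
print(round(report.auroc, 2), report.tp + report.tn, "of", report.n)
```

which prints

```
(80, 128, 141, 1)
1.0 16 of 16
```

i.e. on strongly separated synthetic classes (`separation=0.8`) a
scaled-down configuration reaches AUROC 1.0 and classifies all 16 held-out
recordings correctly. The same pipeline is available from the shell:

```bash
bruitnet simulate --n-normal 60 --n-abnormal 20 --seed 7 --out sim/
bruitnet run-all --seed 7 --out run/        # simulate→augment→featurize→train→evaluate
```

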