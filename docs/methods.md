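# Methods

## Problem setting

An arteriovenous fistula (AVF) is the surgically created artery–vein
connection used as vascular access in hemodialysis. Blood flow through it
produces a bruit audible with a stethoscope; stenosis (narrowing, here
labelled *abnormal* when the fistula diameter falls below 1.8 mm) weakens
the sound and scatters its spectral energy. The package classifies 24–30 s
mono recordings at 16 kHz into *normal* / *abnormal* from that spectral
signature.

## Synthetic bruit generator

Real AVF recordings of this kind are clinical data and not publicly
deposited, so all tests and examples run on a generative stand-in
(`bruit_synth`). The signal model is deliberately minimal — the smallest
construction that reproduces the qualitative class contrast the pipeline is
designed to detect:

- a pulse train of Gaussian-windowed systolic peaks at `heart_rate`
  (default 1.2 beats/s, ±3 % beat-to-beat jitter) forms an amplitude
  envelope with a diastolic floor of 0.35 (the bruit never fully silences);
- broadband turbulence noise: white noise through a one-pole low shelf
  (≈1/f tilt) and a 4th-order Butterworth low-pass at 3 kHz, unit variance,
  scaled to a peak amplitude of 0.18 so clipping is never needed (per-sample
  renormalization would erase the class power contrast);
- the **abnormal** class multiplies the broadband component by
  `1 − 0.5·separation` and superimposes Poisson-timed (1/s) 50 ms tone
  bursts at random frequencies in 300–3000 Hz with amplitude
  `0.35·separation`, reproducing "weaker overall, scattered narrowband"
  energy.

`separation ∈ [0, 1]` is the single effect-size knob: at 0 the classes are
drawn from one distribution (a null case the tests verify by t-test at
n = 50/class); class separability, measured as the AUROC of a 0–2 kHz
band-power threshold, increases monotonically with it. The default 0.8
gives strongly but not perfectly separated classes — comparable to a task a
convolutional classifier should solve nearly perfectly, which is what the
learning tests assert.

**What passing tests show and do not show.** The generator emulates spectral
energy distribution only. It has no hemodynamic model (no mapping from
diameter to sound), no patient covariates, no stethoscope transfer function,
no clinic noise floor, and its within-class variability is far smaller than
real inter-patient variability. Results on it validate the pipeline's
mechanics and learning capacity, not clinical performance.

## Augmentation and splitting

The emulated corpus is 600 normal / 200 abnormal originals. Expansion
rebalances it: each normal original contributes its two random clips
(3–6 s and 18–21 s); each abnormal original contributes six variants (both
clips, both clips with added white noise, and the full recording clean and
noise-added), yielding 1,200 per class. Noise is injected at a measured
SNR (default 20 dB, exact to < 0.1 dB by construction); clip start offsets
are uniform over the feasible range.

Splitting is stratified by label. Overall sizes are floor-rounded
(validation and test) with the remainder going to train; per-class counts
within each split follow largest-remainder apportionment, keeping the class
imbalance of every split at ≤ 1. Splitting happens after augmentation, so
variants of one original can land in different splits; `group_by_parent=True`
(or `--group-by-parent`) keeps each original's family together for
leakage-free evaluation.

## Feature fusion

- Pre-emphasis `y[n] = x[n] − μ·x[n−1]`, μ = 0.97, `y[0] = x[0]`. The
  filter's magnitude response is 1 − μ = 0.03 at DC and rises monotonically
  with frequency (property-tested via the FFT of the impulse response).
- STFT: 25 ms Hann window, 10 ms hop, 512-point FFT; 128 triangular mel
  filters on the HTK scale (2595·log10(1 + f/700)) spanning 0–8 kHz; power
  floored at 1e-10 before the log so digital silence yields a finite
  constant matrix.
- The time axis is standardized to 128 frames by per-row linear
  interpolation, so 3 s clips and 30 s recordings produce the same shape.
  MFCCs are the lowest 13 orthonormal DCT-II coefficients of the log-mel
  columns; since the DCT acts on the band axis and the resize on the time
  axis, the two commute — a test exploits this to check the MFCC path
  against a direct DCT summation oracle.
- Both matrices are min–max normalized per time frame (constant columns map
  to zeros, keeping the [0, 1] range invariant without a 0/0), stacked into
  (141, 128), renormalized, transposed to time-major and given a channel
  axis: (128, 141, 1).

## Classifier

Three blocks of [3×3 conv → LeakyReLU(0.01) → BatchNorm → CBAM → 2×2
max-pool → dropout] with 64/128/256 filters by default. CBAM uses the
canonical internals: channel attention from global average- and max-pooled
descriptors through a shared C → C/r → C bottleneck (r = 16, clamped to C)
with a sigmoid; spatial attention from stacked channel-mean/max maps through
a bias-free 7×7 convolution with a sigmoid; both applied multiplicatively
(spatial attention is computed on the channel-refined map). After pooling,
the (C, 16, 17) map becomes a 16-step sequence with C·17 features per step,
feeding one LSTM layer (128 units), a dense LeakyReLU layer (64 units) with
dropout, and a single sigmoid output; *abnormal* is predicted when
p ≥ 0.5 (ties go to abnormal — the sensitive choice for a screening tool).
Unstated sizes (LSTM/dense width, dropout 0.3, slope 0.01) are common
defaults at this scale and configurable.

Training: Adam (lr 0.001), batch 64, ≤ 300 epochs, early stopping on
validation loss (patience 10, best weights restored). The loss is binary
cross-entropy with probabilities clipped to [1e-7, 1 − 1e-7].

### Numerical engine

The network runs on `bruitnet.nn`, a compact numpy reverse-mode autodiff
core written for this package. Convolutions dispatch between an
im2col + BLAS matmul path and, for single-output-channel maps (the spatial
attention conv), an FFT-convolution path whose gradients are themselves
convolutions; the two paths are cross-checked against each other and all
operators against central finite differences (relative error < 1e-4).
Everything is single-threaded numpy, so runs are bit-deterministic given
the seed. Training casts parameters and activations to float32 (inference
and gradient checks use float64). BatchNorm keeps bias-corrected
exponential running moments (Adam-style correction): with only tens of
updates an uncorrected EMA still carries its arbitrary initialization,
which systematically mis-scales inference activations and was observed to
collapse eval-mode logits in short runs.

## Evaluation

Confusion counts with *abnormal* as positive; precision, recall, F1,
accuracy per the standard definitions; degenerate denominators (e.g. no
predicted positives) report NaN rather than a silently optimistic 0. AUROC
and the ROC curve come from scikit-learn (Mann–Whitney equivalent, ties
averaged) and are cross-checked in tests against an O(N²) concordant-pair
count.

The spectrogram-contrast procedure draws seeded random (normal, abnormal)
pairs — 50 by default — and for each feature type (normalized mel,
normalized MFCC, fused) reports the mean PSNR = 10·log10(MAX²/MSE) and a
global-statistics SSIM (single window, population moments,
C1 = (0.01·MAX)², C2 = (0.03·MAX)², MAX = 1 for normalized images). Lower
values mean the feature exposes a larger between-class difference. How two
populations are reduced to one number is a design choice here (random
pairing, mean over pairs); a windowed SSIM variant is deliberately out of
scope.

## Problem sizes used in tests

The acceptance suite runs the full 600/200 → 2,400 bookkeeping pipeline on
real generated audio. The learning check uses a scaled-down configuration —
200 training / 20 validation / 80 test synthetic recordings at
separation 0.8, conv filters (8, 16, 32), LSTM 32, batch 32, lr 0.002,
12 epochs, three model seeds — chosen as the smallest run that
demonstrates near-perfect separability (AUROC ≥ 0.95 asserted; 1.00
observed for all three seeds). The full 64/128/256 architecture is
exercised in forward-shape and determinism tests.

## Known limitations

- Synthetic-only validation; see the generator caveats above.
- The augmentation multiplicities (2× normal, 6× abnormal) are one
  consistent scheme for reaching class balance from a 3:1 corpus; other
  schemes would be equally valid and the counts are configurable.
- Single-window SSIM differs from the windowed estimator common in image
  libraries; values are not interchangeable between the two.
- One LSTM layer is used; stacking a second is possible via the module API
  but not exposed in `ModelConfig`.
- The default split permits sibling leakage (by design, matching
  split-after-augmentation bookkeeping); use `group_by_parent` for honest
  generalization estimates.
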