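# Methods

This note documents the models, parameters, and design choices behind
`osadetect`, and what its synthetic benchmark does and does not demonstrate.

## Problem setting

Obstructive sleep apnea (OSA) interrupts breathing in episodes of ten seconds
or more, and polysomnography — the clinical gold standard — is costly enough
that single-channel screening is attractive. Apnea episodes leave a robust
fingerprint in a single-lead ECG: a cyclical variation of heart rate
(bradycardia–tachycardia oscillations with a period of roughly 30–60 s),
alongside subtler morphology changes. The package classifies each one-minute
ECG segment as normal breathing (`N`) or disordered breathing (`A`) by
converting the segment into three image modalities and pooling four
convolutional classifiers by weighted soft voting.

## Preprocessing

Each record passes through, in order:

1. **Low-pass** order-4 Butterworth, cutoff 40 Hz — removes high-frequency
   noise while retaining all QRS energy.
2. **Band-pass** order-4 Butterworth, 0.5–15 Hz — removes baseline wander and
   residual muscle noise. Both filters are kept even though the band-pass
   dominates the composite response; the low-pass is applied first.
3. **Median despiking**, kernel 5 samples (50 ms at 100 Hz) — removes
   isolated electrode spikes while preserving the ~80 ms QRS complex. The
   kernel is configurable; edges are reflected.
4. **Segmentation** into one-minute windows (6000 samples at 100 Hz),
   0-based, half-open; the trailing partial minute is discarded, and segment
   count is the minimum of whole minutes and labels.
5. **Per-segment z-score** with the population standard deviation. Per
   segment rather than per record because the segment is the model's input
   unit and per-segment scaling removes slow gain drift; the scope is
   configurable. A constant (flat) segment standardizes to all zeros with a
   warning and is excluded from encoding.

All filtering is zero-phase (forward–backward `sosfiltfilt`), so P/QRS/T
morphology is not skewed; the effective amplitude response is the square of
the single-pass Butterworth magnitude. Tests assert the measured attenuation
against the closed-form digital (bilinear, prewarped) magnitude response; at
probe frequencies approaching Nyquist this differs substantially from the
analog textbook formula `1/√(1+(f/fc)^(2n))`, and the digital response is the
correct reference for what `sosfiltfilt` computes.

## Image encodings

All encoders emit 224×224×3 RGB images in [0, 1] through one pinned,
perceptually uniform colormap (`viridis`), so images are byte-reproducible.

### CWT scalogram

The continuous wavelet transform uses the complex Morlet wavelet
`φ(t) = (bπ)^(-1/2) · exp(−t²/b) · exp(j2πFc t)` with bandwidth `b = 1.5`
and center frequency `Fc = 1.0` — a common parameterization; the method is
insensitive to the exact values because images are min–max normalized.
Coefficients are the discretized correlation
`C(s,τ) = s^(-1/2) Σ_n x[n] φ*((n−τ)/s) Δt` with `Δt = 1/fs` and zero-padded
edges, evaluated at every sample shift. A scale maps to frequency as
`F = Fc·fs/s`. The scale grid is 128 log-spaced scales spanning 0.5–40 Hz —
exactly the band preprocessing retains; grid quantization keeps the
peak-scale law within ~1.7%, comfortably inside the 5% tolerance tested.
`|C|` is min–max normalized, colormapped, then bilinearly resized (with
Gaussian prefilter on shrunk axes) to 224×224, low frequencies at the bottom.
A filter-bank variant (`CwtBank`) shares the segment FFT across scales for
repeated encoding; it is tested to agree with the direct transform to 1e-12.

### Gramian angular fields

A segment is reduced to 224 points by piecewise aggregate approximation
(PAA, exact fractional bins via the cumulative integral), min–max rescaled to
[−1, 1] by `x̃ᵢ = ((xᵢ−max x)+(xᵢ−min x))/(max x−min x)`, mapped to angles
`φ = arccos x̃`, and encoded as `GASF = cos(φᵢ+φⱼ)`, `GADF = sin(φᵢ−φⱼ)`.
Applying PAA *before* the Gram matrix (rather than building the 6000×6000
matrix and shrinking the image) produces the 224×224 geometry directly at
~700× less memory; this is the package's resolution of the otherwise
unspecified 6000→224 reduction. The polar radius `rᵢ = tᵢ/N` is computed and
carried in the type for completeness but does not enter either matrix.
Matrix values map affinely from [−1, 1] to [0, 1] before colormapping.

## Classifiers

Both networks take 224×224×3 inputs and share a stem — 32 7×7 convolutions,
ReLU, 3×3 max pooling — and a head — global average pooling, dropout 0.5,
2-way softmax. Pixel inputs in [0, 1] are centered to [−1, 1] by a fixed
affine layer before the stem; He initialization assumes zero-mean inputs,
and at small widths an uncentered input can freeze the narrow stem in a
dead-ReLU state for unlucky seeds.

* **Residual network**: four residual blocks with 64, 128, 256, 512 filters.
  Each block is two successive convolutions with ReLU after each, plus a 1×1
  projection skip. Body kernel size (3×3), strides, and the head are free
  parameters of the design; the package uses stem stride 2, pool stride 2,
  and a ×2 downsampling per block (first body conv and skip at stride 2) so
  the 224×224 input reduces to a tractable map before global pooling.
* **Inception network**: nine 4-branch inception blocks
  (1×1; 1×1→3×3; 1×1→5×5; 3×3 max pool→1×1 — the classical topology, with
  the six filter counts per block mapped onto the branches in that order),
  with extra 3×3/stride-2 max pools after blocks 2 and 7. "Same" padding
  everywhere avoids branch alignment issues.

A `width_multiplier` scales every filter count (floor 1) so the identical
topology trains quickly on a CPU; structural conformance tests pin it to 1.0.
Networks run on a compact in-package numpy engine (im2col convolutions,
explicit backpropagation, Adam); every layer's analytic gradient is verified
against central finite differences.

## Training and evaluation

Training minimizes cross-entropy with Adam. Library defaults are
conservative (lr 1e-3, batch 32, 20 epochs); the standard benchmark uses
lr 3e-3, batch 16, 4 epochs — at 1e-3 the inception member needs far more
epochs to leave its initial plateau (it is the deepest member and has no
skip connections), while at 3e-3 every member converges within the epoch
budget. All
stochasticity (init, shuffling, dropout) flows from explicit seeds; two runs
with the same seed reproduce loss curves bit-for-bit in a single-threaded
BLAS. Metrics use apnea as the positive class: accuracy `(TP+TN)/total`,
sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`; AUC is the normalized
Mann–Whitney statistic with ties counted half, identical to the trapezoidal
area under the empirical ROC. Cross-validation folds are stratified and
seeded.

## Soft-voting ensemble

The four members — (CWT, inception), (CWT, residual), (GASF, residual),
(GADF, residual) — are fused per segment by a convex combination of their
class probabilities; the fused apnea probability is the ROC score and the
argmax is the label, with exact ties resolved to `A` because a missed apnea
minute is the costlier error. Default weights are the members' validation
accuracies normalized to sum one, measured on a held-out validation split
(10% of segments) carved from the training portion — never on the test
split — so the weights cannot leak test information. A member at or below
chance on a small validation split is floored at half a count to keep its
weight defined. Explicit weights may be supplied in the run config instead.

## Synthetic data generator

The generator produces what the classifiers must learn to separate, and
nothing more: per-minute-labeled 100 Hz single-lead ECG in which `A` minutes
carry slow cyclic RR-interval modulation (period 45 s, default depth 0.15 —
the cyclical variation of heart rate accompanying obstructive events) and
`N` minutes carry respiratory sinus arrhythmia (0.25 Hz, depth 0.05, typical
resting values). Beats are a fixed five-Gaussian P-QRS-T template placed at
cumulative RR times; 1% multiplicative RR jitter, 0.1 mV baseline wander at
0.3 Hz, and 0.05 mV white noise are added; mean heart rate is 70 bpm with a
±10% uniform per-record spread. Apnea minutes come in contiguous episodes of
at least two minutes, matching how events cluster clinically.

What it does **not** emulate: morphology changes during events, ectopy,
electrode artifacts beyond white noise/wander, inter-patient template
variation, or respiration/SpO₂ channels. Passing the synthetic benchmark
therefore demonstrates that the pipeline is wired correctly and that the
encoders preserve heart-rate-dynamics information well enough for small CNNs
to recover it — not that the trained weights transfer to clinical ECG.

## Benchmark problem sizes

The package's standard benchmark generates 20 records × 20 minutes
(400 labeled minutes, half apneic), encodes all three modalities, trains the
four members for 4 epochs at width multiplier 0.125, and evaluates on a
stratified 20% held-out test split with a 10% validation split for the
ensemble weights. These sizes keep a full run to a few minutes on one CPU
core while leaving the two classes separable far above chance. On the seeded
benchmark the CWT→residual member dominates, reaching ~1.0 held-out accuracy
across every seed tried; the GASF/GADF members land near 0.6–0.8 — the same
ordering the full-scale method exhibits on clinical data, where GAF images
are the weaker single-modality inputs. The inception member is the most
seed-sensitive at this width: on some seeds it reaches ~0.9 within the
4-epoch budget, on others it stays on its initial plateau, in which case the
accuracy-proportional fusion down-weights it. The ensemble reaches ≥0.85
held-out accuracy and ≥0.9 AUC in either regime.

## Numerical choices and degenerate inputs

* Filters validate cutoffs strictly inside (0, Nyquist); signals must exceed
  3× the filter order.
* A constant series is a validation error for GAF rescaling; flat segments
  are dropped upstream (with a warning) from all three modalities to keep
  them aligned.
* A constant-magnitude coefficient matrix renders at the colormap midpoint
  (no division by zero in min–max normalization).
* Metric ratios with zero denominators return NaN with a warning rather than
  raising, so single-class evaluations degrade visibly.
* Max-pool gradients under ties are split equally among maximizers — a
  deterministic subgradient.
* The Morlet kernel is truncated where its envelope falls below ~1e-8 of the
  peak.
* Stage seeds expand from the global seed via `SeedSequence` and stay below
  2³¹.

## Known limitations

* The WFDB I/O supports the subset of the format family the target data
  uses: format-16 single-channel signals and MIT annotation files with
  N/A-coded per-minute labels. No EDF, no multi-lead, no format 212.
* The numpy engine is CPU-only and single-device; full-width training on
  tens of thousands of images is out of its intended scope.
* Per-recording severity indices (AHI) and hypopnea/central-apnea
  differentiation are out of scope; the unit of decision is the minute.
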