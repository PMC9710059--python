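# Methods

`leadconv` reconstructs the twelve standard electrocardiogram (ECG) leads
from short, blindly-segmented windows of a single limb lead.  This note
describes the models, the preprocessing, the synthetic ensemble used for
development and testing, and the numerical choices that were genuinely
open.

## Problem setting

The standard clinical ECG records twelve leads — I, II, III, aVR, aVL,
aVF (limb leads) and V1–V6 (chest leads) — but needs ten electrodes.
Interlead conversion learns a map from one recorded lead to the missing
ones.  The setting here is deliberately hard: the input is a fixed-length
window of a single limb lead cut *blindly*, i.e. with no R-peak detection
or beat alignment, so the model must cope with arbitrary beat phase.

The six limb leads are algebraically dependent: at every instant
III = II − I, aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2
(Einthoven/Goldberger).  The chest leads are not derivable from limb
leads.  These identities shape expectations: from lead II, targets that
are close to affine functions of II should convert well, while targets
dominated by the independent component of lead I are harder.

## Preprocessing

Records are processed per lead and per window:

1. **Resampling** to the target rate with polyphase band-limited
   interpolation (only when source and target rates differ).
2. **Blind segmentation** into consecutive non-overlapping windows
   starting at sample 0; a trailing remainder shorter than one window is
   dropped.  Default window 5 s; the test protocol uses 2.5 s at 250 Hz.
3. **Band-pass filtering** with a second-order Butterworth, pass band
   1–40 Hz, applied forward and backward (`sosfiltfilt`).  Zero-phase
   application avoids displacing ECG landmarks; the effective magnitude
   response is the squared Butterworth response, which the tests verify
   against the analytic curve within 1 dB.
4. **Min–max normalisation** per segment and lead onto [−1, 1]:
   `x_n = 2 (x − x_min)/(x_max − x_min) − 1`.  Windows in which any
   required lead is flat are dropped as a whole group (the map is
   undefined) and logged; flatness is detected on the raw window, since
   filtering would turn an exactly constant window into numerical noise.

Filtering precedes normalisation by default; the reverse order is
available via `normalise_before_filter` (the filtered output is then
re-normalised so the [−1, 1] span contract still holds).  Splits are
always subject-disjoint: a subject's records appear in exactly one of
train/validation/test.  Without an explicit test-subject list, subjects
are shuffled with the split seed and assigned greedily to approximate the
63/7/30 proportions by sample count, with a guarantee that every set with
a positive fraction receives at least one subject.

## Models

All conversion models map a normalised reference-lead window to one
window per target lead.  Three convolutional encoder-decoder families
share a skeleton, implemented on a small numpy layer stack (convolutions
via im2col + GEMM, manual backpropagation, verified by numerical gradient
checks):

* **U-Net** (`unet`): `depth` encoder blocks (two same-padding
  convolutions, each with batch normalisation and ReLU, then factor-2
  max-pooling; channel count doubles per block from `base_channels`), a
  two-convolution bottleneck (channels double once), and mirrored decoder
  blocks (linear-interpolation upsampling plus two convolutions) with
  skip connections concatenating each encoder block's pre-pooling feature
  map into the matching decoder block.  The single-channel output head
  uses tanh, so predictions lie strictly inside (−1, 1).
* **Autoencoder** (`ae`): identical minus the skip connections.
* **Label-refinement network** (`lrn`): the U-Net plus an auxiliary
  single-channel tanh head on every decoder block, supervised against the
  target average-pooled to that resolution (coarse-to-fine supervision).

One-to-all conversion uses either one **shared encoder** feeding all
target-lead decoders or one **individual** encoder-decoder pair per
target.  A **pointwise baseline** maps each time point's amplitude
through a fully-connected network (default 3 × 64 units); it has no
temporal context by construction and serves as the control for how much
of the conversion requires waveform context.

Decoder "transposed convolutions" at stride 1 are parameterised as
ordinary correlations with learned kernels — the same family of linear
maps, just a different indexing convention.  Inputs whose length is not a
multiple of `2^depth` (e.g. 625 samples at depth 3) are symmetrically
edge-padded to the next multiple (632) before the encoder and cropped
back after the head; 5000-sample windows at depth 3 need no padding
(5000 = 8 · 625).

Defaults: depth 3, base 16 channels, kernel 9.  The exact widths are not
contractual; scaled-down runs in the tests use base 8 to keep CPU time
modest.  Parameter-count orderings (shared < individual, U-Net > AE at
equal config) are asserted structurally.

## Training protocol

The objective is the mean absolute error (l1) between predictions and
targets, summed over target leads; for the LRN, plus equally weighted l1
terms at each auxiliary resolution.  Optimisation uses Adam with initial
learning rate 1e-3 (no schedule, no gradient clipping; a non-finite loss
aborts with diagnostics), batches reshuffled each epoch with the run
seed, batch size 32 for the shared scheme and 16 for individual
encoders, for at most 500 epochs with early stopping at patience 50
(defaults; the scaled-down test protocol uses ≤ 60 epochs, patience 10).
The monitored quantity is the validation multi-lead l1; training stops
once `epoch − best_epoch ≥ patience`, and the parameters (including
batch-norm running statistics) of the best validation epoch are restored
before evaluation.  With a fixed seed the whole run is deterministic on a
given platform: the tests assert bit-identical histories and reports
across reruns.

## Metrics

Per segment and target lead: Pearson r (signed; segments on which r is
undefined — a constant converted or measured signal — are excluded from
the r aggregation but counted in the report), RMSE on the normalised
scale, and a 1-D SSIM: uniform sliding windows (default 111 samples),
sample (ddof = 1) variances and covariance, constants
C1 = (0.01 · data_range)², C2 = (0.03 · data_range)², data_range = 2 for
the [−1, 1] scale, averaged over all full windows.  Per-lead reports give
the average and median r and average RMSE/SSIM, with the per-metric
segment counts; stratified reports group by diagnostic label.  All three
metrics are pinned to naive double-loop references at 1e-10, and the SSIM
additionally cross-checked against scikit-image's implementation.

A note on SSIM signs: for anti-correlated signals the windowed product is
negative only where window means are small relative to C1; on zero-mean
noise the luminance term is itself negative and the product positive.
The negativity test therefore uses a period-aligned sinusoid.

## Synthetic ensemble

No clinical data ships with the package; the generator produces records
with the interlead structure the method exploits:

* Each subject has an electrical axis α ~ U(45°, 80°), a sum-of-Gaussians
  beat (P, Q, R, S, T; amplitudes/centres/widths jittered ±10% per
  subject), a smoother secondary morphology component placed between the
  P/R/T centres, a heart rate ~ U(55, 95) bpm, and chest-lead gains.
* Lead I = cos(α) · s_long; lead II = cos(α − 60°) · s_long + g · s_aug
  with g ≈ 0.6.  The secondary component keeps corr(I, II) moderate
  (≈ 0.45 on the default ensemble, as observed between real limb leads)
  while III/aVR/aVF remain strongly (anti-)correlated with II.
* III, aVR, aVL, aVF follow the Einthoven/Goldberger identities exactly
  before noise; the tests assert ≤ 1e-12 residuals with noise disabled.
* Chest leads are linear mixtures of I and II (sign pattern following the
  usual precordial progression) through a mild tanh nonlinearity.
* Beat-to-beat RR intervals are i.i.d. with CV 5%; baseline wander is a
  0.33 Hz sinusoid (amplitude 0.08) and noise is additive Gaussian
  (sd 0.02 by default).
* Optional labels (`superclass` scheme) draw one of NORM/MI/STTC/CD/HYP
  per record for exercising stratified reports; they carry no
  physiological meaning.

What the ensemble does *not* emulate: pathology-specific morphology,
electrode-motion artefacts, mains interference, inter-database
acquisition differences, or genuinely independent chest-lead information
(V1–V6 here are functions of I and II plus noise, so their convertibility
is optimistic relative to real chest leads).  Passing tests therefore
demonstrate that the pipeline learns and evaluates correctly under a
controlled, known-structure ensemble — not clinical-grade conversion.

### Problem sizes in the tests

The end-to-end checks run 60 subjects (1 record × 10 s at 500 Hz each),
preprocessed to 2.5 s windows at 250 Hz (≈ 480 windows), with a depth-3,
base-8 shared U-Net — sizes chosen so the whole suite completes in
minutes on one CPU while leaving the learning problem non-trivial.

### The delay probe

The pointwise baseline is probed on a target equal to the reference
delayed by 40 ms.  On a noise-free periodic waveform a pointwise map is
partially predictive even across a lag (the cycle is stereotyped, so
instantaneous amplitude constrains the phase), which real
multi-subject blindly-segmented ECG does not exhibit.  The probe
therefore uses a noise-rich configuration (noise sd 0.6): the stochastic
component cannot be carried across the lag by any per-time-point map
(band-limited 1–40 Hz noise has autocorrelation ≈ −0.09 at 40 ms), while
a convolutional model represents the delay trivially.  Measured on
held-out subjects: pointwise r ≈ 0.16, U-Net r ≈ 0.87.

## Known limitations

* The numpy training loop is single-threaded and unbatched across
  decoders; full-scale replication (5 s / 1 kHz windows, hundreds of
  subjects, 500 epochs) is possible but slow compared to a GPU stack.
* WFDB support covers the common subset (format 16, one interleaved
  signal file, per-signal gain/baseline) — enough for round-tripping the
  package's own records and the standard 12-lead PhysioNet layout, not
  the full format zoo.
* Min–max normalisation ties the output scale to each window's extremes;
  baseline offsets between measured and converted signals are an
  expected artefact of this choice.
* SSIM values depend on its parameterisation (window, constants, data
  range); reports embed the parameters used so numbers are comparable
  across runs.
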