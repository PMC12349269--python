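# Methods

This note records the scientific and numerical choices behind the
package: what each stage computes, which parameters matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## Problem setting

A phonoenterogram (PEG) is a stethoscope recording of bowel sounds from
the abdominal wall, typically 44.1 kHz mono with usable signal in roughly
the 250–5000 Hz band. Annotators mark *prominent* sounds (clearly audible
unamplified); everything else — baseline and "obscure" sounds audible only
under heavy amplification — is background. Two prominent sounds are
distinct only when baseline sound separates them, which is why
overlapping or abutting prominent intervals are merged before any
downstream processing. The detection task is binary classification of
fixed-length audio segments, then aggregation of window scores into timed
events.

## Signal conditioning

- **High-pass filter**: Butterworth, cutoff 50 Hz, order 4, applied
  zero-phase (forward–backward). The cutoff removes respiration/motion
  rumble below the bowel-sound band. Order and phase handling are this
  package's choices: order 4 is standard for physiological audio, and
  zero-phase application preserves the timing of transient onsets while
  squaring the magnitude response (an order-4 single pass gives ≈56 dB at
  f/fc = 0.2; the tests require ≥50 dB at 10 Hz, which either reading
  satisfies). A causal variant with chunk-to-chunk state
  (`StreamingHighpass`) exists for live use and is bit-equivalent to a
  single `sosfilt` pass.
- **Normalization**: per-recording peak normalization before int16
  quantization (divide by max |sample|, scale by 32767, round half away
  from zero). With no stated reference level, peak normalization is the
  one choice that guarantees full 16-bit range use. The same gain is
  applied before feature extraction, and the streaming detector treats it
  as a one-off per-recording calibration.
- **Multi-channel audio** is averaged to mono on read; no resampling.

## Segmentation (integer-millisecond arithmetic)

Segment length L = 375 ms, overlap 200 ms, hop = 175 ms. All boundary
arithmetic is in integer milliseconds so results are exact and
platform-independent; the sample slice for start t is
floor(t·sr/1000) … +floor(L·sr/1000), giving every segment an identical
sample count (16537 at 44.1 kHz).

- Short prominent interval [s, e] (length ≤ L): one segment at
  floor((s+e−L)/2), which centers the interval within half a millisecond;
  clamped into [0, duration−L] at file boundaries. Zero padding
  (symmetric) occurs only when the whole recording is shorter than L.
- Long interval: starts s, s+hop, … while start+L ≤ e, plus one final
  end-aligned segment at e−L when the last hopped segment falls short of
  e, so the interval's tail is always covered.
- Non-prominent segments tile the gaps between prominent intervals —
  including the stretch before the first and after the last — at the same
  hop, discarding remainders shorter than L. Whether the head-of-file
  stretch should count was open; including it is symmetric with the tail
  rule and only adds background examples.
- Labels come from the extraction pipeline (an interval's segments are
  prominent, gap segments are not), not from post-hoc overlap fractions.

A brute-force enumerator over all millisecond offsets reproduces every
start list in the tests.

## MFCC features

Hamming-windowed STFT with n_fft = 1024 and hop 512, no center padding:
31 frames per 16537-sample segment — the only unconstrained (n_fft, hop)
pair consistent with "about 30" frames at this sampling rate. Power
spectra pass through 32 unit-peak triangular filters whose centers are
equally spaced on the mel scale m(f) = 2595·log₁₀(1+f/700) between 50 Hz
(the high-pass cutoff) and 5 kHz (the stethoscope's upper band edge).
Log compression uses the natural log with floor ε = 1e-10 — any base is
an affine rescaling the classifier absorbs, and the floor keeps silent
frames finite. The DCT-II is applied as the plain cosine sum
MFCC(j) = Σᵢ₌₁..M L(i)·cos(πj(2i−1)/2M) without the conventional factor 2
or orthonormal scaling, and coefficients j = 0…12 are retained, including
the energy-like j = 0. No liftering and no delta features. The triangles
are not area-normalized: the log-mel formula as used has no normalization
term, and peak-1 triangles keep the filter response interpretable.

## Classifier

Input (31, 13). Conv1D stem: kernel 3, stride 1, same padding, 13→64
channels, then layer norm and ReLU. The published configuration lists a
64-filter stem and a 128-wide encoder; the minimal reconciliation — a
learned 64→128 linear projection after the stem — is used here. Fixed
sinusoidal positional encoding is added after the projection (a switch
disables it; attention is otherwise permutation-invariant over frames).
Four post-norm encoder blocks follow: 8-head self-attention with
d_k = 128/8 = 16, softmax(QKᵀ/√d_k)·V per head, heads concatenated and
mixed; each sub-layer is followed by dropout (0.1), a residual add and
layer norm; the feed-forward network is 128→256→128 with ReLU. Global
average pooling over frames, dense 128→64 (ReLU), dense 64→1 (sigmoid).
Total learned parameters: 549,249, with a closed-form count verified
against introspection.

The network and optimizer are implemented directly on numpy with
hand-written backward passes; every layer's gradient is pinned by
finite-difference checks in the test suite. Weights initialize from a
uniform fan-in scheme with a seeded generator, so config + seed fully
determine the model. A `reduced()` configuration (d_model 32, 2 blocks,
4 heads, FFN 64) keeps the identical topology at ~1/28 the parameter
count for single-CPU experiments; the end-to-end tests and the
acceptance script use it.

## Training protocol

Stratified 60/20/20 train/validation/test split at segment granularity
(validation and test sizes round to nearest within each class; train
absorbs the remainder). Segment-level splitting is the default, matching
the source protocol; a recording-level option assigns whole recordings
to one partition to rule out leakage between overlapping segments of the
same recording (the streaming-detector evaluation always uses recordings
the classifier never saw, regardless of split unit). Adam at lr 0.001 minimizes binary cross-entropy (computed in
the numerically stable logits form) with batch 512 for up to 150 epochs.
Validation loss drives all three callbacks: best-weights checkpointing
(the returned model is the checkpoint, not the final state),
reduce-on-plateau (factor 0.5, patience 5, floor 1e-5 — the scheduler is
named in the source configuration but its constants are this package's
choice), and early stopping with patience 10. No class weighting or
resampling is applied despite the ~10:1 imbalance, matching the source
protocol; a class-weight flag exists but is off by default. Per-epoch
loss, validation loss, accuracy, AUC, precision and recall are recorded
and persisted as a reloadable array archive.

AUC is computed threshold-free over the score ranking (scikit-learn's
implementation, cross-checked in tests against a pairwise-concordance
oracle with ties counted ½); the confusion matrix and derived metrics
use a 0.5 threshold, the natural operating point of a sigmoid head.
A single-class evaluation set raises an error rather than reporting an
undefined AUC.

## Streaming detection

Windows of 375 ms at the 175 ms training hop are featurized and scored
in causal order; each score depends only on samples inside its window.
Consecutive super-threshold windows whose spans overlap merge into one
event (union span, max score); `min_gap_ms` (default 0) optionally
bridges short sub-threshold holes. The default of merging only
overlapping windows follows from the distinctness convention: any
baseline gap separates events. Event-level scoring uses greedy one-to-one
overlap matching with optional ±tolerance dilation; with no detections,
precision is reported as 0 with an explicit flag.

## Synthetic data

The generator emulates the gross statistics of annotated PEG recordings,
not bowel physiology — no public acoustic model of bowel sounds exists,
so burst morphology is a construction:

- **Background**: white Gaussian noise plus a <50 Hz low-pass-filtered
  component, power-mixed by `background_lf_weight` (default 0.3) and
  scaled to RMS 0.02. The low-frequency part exists precisely so the
  50 Hz high-pass has something real to remove.
- **Events**: Poisson onsets at 12/min by default; each burst is a damped
  sinusoid (time constant = duration/4) with a raised-cosine onset ramp
  over the first 10%, carrier uniform in 250–1500 Hz, duration uniform in
  60–900 ms. A single global amplitude factor calibrates the realized
  in-event/background RMS ratio to `snr_db` (default 10 dB, accurate to
  ~0.1 dB in practice). Overlapping bursts merge into one ground-truth
  interval. If the summed waveform would clip, the whole signal is
  rescaled (SNR-preserving) to peak 0.99.
- Defaults give a prominent-segment fraction near 9% — the same order as
  a clinically annotated corpus (~15%) — and per-recording seeds spawn
  deterministically from the master seed.

What passing tests on this data shows: the pipeline's plumbing, feature
mathematics, optimization and event logic are correct, and the classifier
can learn a well-posed burst-vs-background discrimination at a realistic
SNR. What it does not show: performance on clinical recordings, whose
event morphology, artifact structure and annotator noise are far richer;
headline metrics on synthetic data (AUC ≈ 1.0 at 10 dB SNR) exceed what
real PEG audio yields and must not be read as clinical performance.

## Problem sizes and numerical choices

The end-to-end test and the acceptance script use 8 two-minute
recordings (~5000 segments, ~3000 training) and the reduced-width model
for at most 30 epochs — sizes chosen so the whole computation is
comfortable on one CPU while still exceeding 3000 training segments.
Sweep runs scale the overlap with segment length (keeping the 200/375
fraction) because a 200 ms overlap is meaningless for 125–250 ms
segments. Label Studio time offsets convert to integer milliseconds by
round-half-up with a 1e-9 guard against binary representation of exact
half-milliseconds. Int16 encoding writes at ×32767 and reads at ÷32768,
the asymmetric convention shared by common audio libraries; round trips
are accurate to one quantization step.

## Known limitations

- No physiological realism in the synthetic bursts; no subject-level
  variability, sensor artifacts, or ambient noise models.
- The classifier is CPU-bound numpy; it is meant for research-scale
  corpora, not GPU-scale training.
- Metrics on synthetic data saturate; comparative conclusions (e.g.,
  segment-size sweeps) should be drawn on real recordings.
- The detector's per-recording gain calibration assumes the recording's
  peak is representative; adaptive gain for open-ended streams is not
  implemented.
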