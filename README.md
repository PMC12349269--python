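# bowelsound

Detection of prominent bowel sounds in phonoenterogram (PEG) recordings —
abdominal-stethoscope audio — for researchers working on non-invasive
gastrointestinal motility assessment.

Auscultation of bowel sounds is subjective and poorly reproducible; an
automated detector turns a PEG recording into an objective sequence of
timed sound events. This package implements a complete, tested detection
pipeline:

1. **Signal conditioning** — mono PCM WAV ingestion, an order-4 zero-phase
   Butterworth high-pass at 50 Hz (removes respiration/motion rumble), peak
   normalization, 16-bit quantization.
2. **Segmentation** — annotated recordings are cut into fixed **375 ms**
   segments with **200 ms** overlap. A prominent interval shorter than a
   segment is centered in one segment (clamped at file boundaries); longer
   intervals are tiled at the 175 ms hop with one end-aligned tail segment.
   Quiet gaps between prominent intervals are tiled the same way and
   labeled non-prominent.
3. **Features** — MFCCs computed from first principles: Hamming-windowed
   STFT (`n_fft` 1024, hop 512), a 32-filter triangular mel bank on
   m(f) = 2595·log₁₀(1 + f/700) between 50 Hz and 5 kHz, natural-log
   compression L(i) = ln(ε + Σₖ|X(k)|²H(i,k)), and an unnormalized DCT-II
   MFCC(j) = Σᵢ L(i)·cos(πj(2i−1)/2M), keeping coefficients j = 0…12.
   A 375 ms segment at 44.1 kHz yields a 31 × 13 feature matrix.
4. **Classifier** — a Conv1D-augmented transformer: a kernel-3, 64-filter
   conv stem (layer norm, ReLU) projected to a 128-wide embedding, 4
   post-norm encoder blocks with 8-head scaled dot-product self-attention
   (softmax(QKᵀ/√d_k)·V, d_k = 16) and 128→256→128 ReLU feed-forward
   networks, global average pooling, then dense 128→64→1 with a sigmoid.
   Implemented on numpy with hand-written backprop, verified by
   finite-difference gradient checks.
5. **Training** — stratified 60/20/20 split, Adam (lr 0.001), binary
   cross-entropy, batch 512, up to 150 epochs with best-validation-loss
   checkpointing, reduce-on-plateau, and patience-10 early stopping.
6. **Streaming detection** — sliding windows at the training geometry are
   scored and consecutive super-threshold windows merge into timed events
   with event-level precision/recall/F1 against ground truth.

Clinical PEG audio is not publicly shareable, so the package includes a
**synthetic phonoenterogram generator** (damped-sinusoid bursts in the
250–1500 Hz band at Poisson onset times over colored background noise,
with exact ground-truth intervals and calibrated SNR) that makes the
entire pipeline reproducible and testable.

## Worked example

```python
from bowelsound.synthdata import SynthConfig, generate_recording, realized_snr
from bowelsound.annotations import AnnotatedRecording
from bowelsound.segmentation import build_dataset
from bowelsound.mfcc import mfcc_pipeline

cfg = SynthConfig(duration_ms=30_000, event_rate_per_min=12.0, snr_db=10.0, seed=7)
synth = generate_recording(cfg)
print(f"events: {len(synth.intervals)}")
print(f"realized SNR: {realized_snr(synth):.2f} dB")

ann = AnnotatedRecording(synth.recording, synth.intervals, recording_id="demo")
ds = build_dataset([ann])
print(f"segments: {len(ds)} ({ds.n_prominent} prominent, "
      f"{ds.n_non_prominent} non-prominent)")
print(f"MFCC shape per segment: {mfcc_pipeline(ds.segments[0].samples, 44100).shape}")
```

prints

```
events: 8
realized SNR: 9.98 dB
segments: 152 (18 prominent, 134 non-prominent)
MFCC shape per segment: (31, 13)
```

A 30-second simulated recording at 12 events/min produced 8 merged
prominent intervals; the generator hit its 10 dB in-event/background SNR
target to within 0.02 dB; segmentation yielded 152 fixed-length segments
of which ~12% are prominent; and each segment featurizes to the 31 × 13
MFCC matrix the classifier consumes.

The same flow is available from the shell:

```bash
bowelsound simulate --n 8 --duration-ms 120000 --rate 12 --snr-db 10 --seed 7 --out corpus/
bowelsound segment  --audio corpus/ --out segments/
bowelsound run      --out run/ --seed 1     # full pipeline incl. training
```

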