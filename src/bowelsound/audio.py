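"""Audio ingestion and preprocessing for phonoenterogram (PEG) recordings.

A phonoenterogram is a stethoscope recording of bowel sounds captured from
the abdominal wall. This module covers the signal-conditioning front end of
the detection pipeline: reading PCM WAV files into a canonical mono float
representation, removing low-frequency noise (respiration, motion, mains
rumble) with a Butterworth high-pass filter, peak normalization with 16-bit
quantization, and the amplification utility annotators use to audition
faint sounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfilt, sosfilt_zi, sosfiltfilt

__all__ = [
    "AudioRecording",
    "FilterSpec",
    "read_wav",
    "write_wav",
    "highpass",
    "normalize_to_int16",
    "amplify",
    "StreamingHighpass",
]

# Scaling applied when mapping integer PCM to float: int16 full negative
# scale is -32768 but we divide by 32768 so +32767 maps just under +1.0,
# the convention librosa/soundfile also use.
_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform with its sample rate.

    ``samples`` is float64 in [-1, 1]; ``duration_ms`` is the floor of the
    duration in integer milliseconds, the canonical time unit downstream.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioRecording is mono: samples must be 1-D")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_ms(self) -> int:
        return int(self.n_samples * 1000 // self.sample_rate_hz)

    def ms_to_sample(self, t_ms: int) -> int:
        return int(t_ms * self.sample_rate_hz // 1000)


@dataclass(frozen=True)
class FilterSpec:
    """High-pass Butterworth specification.

    The 50 Hz default cutoff removes baseline rumble below the bowel-sound
    band; order 4 with zero-phase (forward-backward) application is standard
    for transient physiological audio because it preserves onset timing while
    doubling the effective attenuation slope.
    """

    cutoff_hz: float = 50.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sample_rate_hz: int) -> np.ndarray:
        nyquist = sample_rate_hz / 2.0
        if self.cutoff_hz >= nyquist:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is not below Nyquist {nyquist} Hz"
            )
        return butter(self.order, self.cutoff_hz, btype="highpass",
                      fs=sample_rate_hz, output="sos")


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file as a mono float recording in [-1, 1].

    Integer encodings (8/16/24/32-bit) are rescaled by their full-scale
    value; float files are taken as-is. Multi-channel audio is averaged to
    mono — the stethoscope channel of interest is mono, and averaging is the
    unbiased reduction. The native sample rate is preserved (no resampling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sample_rate, data = wavfile.read(str(path))
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.int16, np.int32):
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(samples=samples, sample_rate_hz=int(sample_rate))


def write_wav(path: str | Path, rec: AudioRecording) -> Path:
    """Write a recording as 16-bit PCM WAV (values clipped to [-1, 1])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), rec.sample_rate_hz, pcm)
    return path


def highpass(rec: AudioRecording, spec: FilterSpec = FilterSpec()) -> AudioRecording:
    """Apply the Butterworth high-pass filter of ``spec``.

    With ``zero_phase`` the filter runs forward then backward
    (``sosfiltfilt``), which cancels phase distortion and squares the
    magnitude response. Output length equals input length either way.
    """
    sos = spec.sos(rec.sample_rate_hz)
    if spec.zero_phase:
        filtered = sosfiltfilt(sos, rec.samples)
    else:
        filtered = sosfilt(sos, rec.samples)
    return AudioRecording(samples=filtered, sample_rate_hz=rec.sample_rate_hz)


class StreamingHighpass:
    """Causal high-pass filter with state carried across chunks.

    Feeding a signal chunk-by-chunk produces bit-identical output to a
    single ``sosfilt`` pass over the concatenation, which is what a live
    detector needs.
    """

    def __init__(self, spec: FilterSpec, sample_rate_hz: int):
        self._sos = spec.sos(sample_rate_hz)
        self._zi = sosfilt_zi(self._sos) * 0.0

    def process(self, chunk: np.ndarray) -> np.ndarray:
        out, self._zi = sosfilt(self._sos, np.asarray(chunk, dtype=np.float64),
                                zi=self._zi)
        return out


def normalize_to_int16(rec: AudioRecording) -> np.ndarray:
    """Peak-normalize and quantize to int16.

    The waveform is divided by its peak magnitude (if nonzero), scaled by
    32767 and rounded half away from zero, so output spans the full
    [-32767, 32767] range. An all-zero input passes through as zeros.
    """
    peak = float(np.max(np.abs(rec.samples))) if rec.n_samples else 0.0
    if peak == 0.0:
        return np.zeros(rec.n_samples, dtype=np.int16)
    scaled = rec.samples / peak * 32767.0
    # np.round is banker's; half-away-from-zero keeps +/-0.5 symmetric
    quantized = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return quantized.astype(np.int16)


def amplify(rec: AudioRecording, factor: float) -> AudioRecording:
    """Scale the waveform by ``factor``, hard-clipping to [-1, 1].

    Mirrors the 4x/16x amplification annotators apply when auditioning
    faint bowel sounds.
    """
    if factor <= 0:
        raise ValueError("amplification factor must be positive")
    return AudioRecording(samples=np.clip(rec.samples * factor, -1.0, 1.0),
                          sample_rate_hz=rec.sample_rate_hz)
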