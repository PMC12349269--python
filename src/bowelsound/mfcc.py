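"""Mel-frequency cepstral coefficients, computed from first principles.

The feature front end for the classifier is the classical MFCC chain:

1. Short-time Fourier transform: frames of ``n_fft`` samples at hop
   ``hop_length``, Hamming-windowed, power spectrum |X(k)|^2 retained for
   k = 0..n_fft/2.
2. Mel filterbank: M triangular filters with unit peak, centers equally
   spaced on the mel scale m(f) = 2595 * log10(1 + f/700) between
   ``fmin_hz`` and ``fmax_hz``.
3. Log compression: L(i) = ln(eps + sum_k |X(k)|^2 * H(i, k)).
4. Discrete cosine transform (type II, unnormalized):
   MFCC(j) = sum_{i=1..M} L(i) * cos(pi * j * (2i - 1) / (2M)),
   keeping the first ``n_coeffs`` coefficients j = 0..n_coeffs-1.

Defaults (n_fft 1024, hop 512, no center padding) give a 31 x 13 feature
matrix for a 375 ms segment at 44.1 kHz. The filterbank spans 50 Hz (the
high-pass cutoff) to 5 kHz (the stethoscope's upper band edge). The log is
natural; any other base is an affine rescaling the classifier absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MfccConfig",
    "FeatureMatrix",
    "hz_to_mel",
    "mel_to_hz",
    "frame_signal",
    "stft_power",
    "mel_filterbank",
    "log_mel",
    "dct_coeffs",
    "mfcc_pipeline",
    "mfcc_batch",
    "n_frames",
]


@dataclass(frozen=True)
class MfccConfig:
    n_fft: int = 1024
    hop_length: int = 512
    n_mels: int = 32
    n_coeffs: int = 13
    fmin_hz: float = 50.0
    fmax_hz: float = 5000.0
    log_floor: float = 1e-10
    # window is fixed Hamming; exposed here only for documentation

    def __post_init__(self) -> None:
        if self.n_coeffs > self.n_mels:
            raise ValueError("n_coeffs must be <= n_mels")
        if not 0 <= self.fmin_hz < self.fmax_hz:
            raise ValueError("need 0 <= fmin_hz < fmax_hz")
        if self.n_fft < self.hop_length:
            raise ValueError("n_fft must be >= hop_length")


@dataclass(frozen=True)
class FeatureMatrix:
    """frames x n_coeffs MFCC matrix with per-frame start times in ms."""

    values: np.ndarray
    frame_times_ms: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


def hz_to_mel(f: float | np.ndarray) -> float | np.ndarray:
    """Mel scale: m(f) = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m: float | np.ndarray) -> float | np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def n_frames(n_samples: int, cfg: MfccConfig) -> int:
    """Frame count without center padding: 1 + floor((N - n_fft) / hop)."""
    if n_samples < cfg.n_fft:
        raise ValueError(
            f"segment of {n_samples} samples is shorter than n_fft={cfg.n_fft}"
        )
    return 1 + (n_samples - cfg.n_fft) // cfg.hop_length


def frame_signal(x: np.ndarray, cfg: MfccConfig) -> np.ndarray:
    """Slice x into (frames, n_fft) with hop ``hop_length`` (no padding)."""
    x = np.asarray(x, dtype=np.float64)
    count = n_frames(x.shape[0], cfg)
    idx = np.arange(cfg.n_fft)[None, :] + cfg.hop_length * np.arange(count)[:, None]
    return x[idx]


def stft_power(x: np.ndarray, cfg: MfccConfig = MfccConfig()) -> np.ndarray:
    """Hamming-windowed per-frame power spectrum, (frames, n_fft/2 + 1)."""
    frames = frame_signal(x, cfg) * np.hamming(cfg.n_fft)
    spectrum = np.fft.rfft(frames, n=cfg.n_fft, axis=1)
    return np.abs(spectrum) ** 2


def mel_filterbank(cfg: MfccConfig, sample_rate_hz: int) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_fft/2 + 1), unit peak per filter.

    Center frequencies are the n_mels interior points of an equally spaced
    grid of n_mels + 2 points on the mel axis between m(fmin) and m(fmax);
    each triangle rises from the previous center and falls to the next.
    Triangles are evaluated on the continuous frequency of each FFT bin, so
    peak bin amplitude can be slightly below 1 when a center falls between
    bins; the apex of filter i is still the maximum of its row.
    """
    nyquist = sample_rate_hz / 2.0
    if cfg.fmax_hz > nyquist:
        raise ValueError(f"fmax {cfg.fmax_hz} Hz exceeds Nyquist {nyquist} Hz")
    n_bins = cfg.n_fft // 2 + 1
    mel_points = np.linspace(hz_to_mel(cfg.fmin_hz), hz_to_mel(cfg.fmax_hz),
                             cfg.n_mels + 2)
    hz_points = np.asarray(mel_to_hz(mel_points))
    bin_freqs = np.arange(n_bins) * sample_rate_hz / cfg.n_fft

    fb = np.zeros((cfg.n_mels, n_bins))
    for i in range(cfg.n_mels):
        left, center, right = hz_points[i], hz_points[i + 1], hz_points[i + 2]
        rising = (bin_freqs - left) / (center - left)
        falling = (right - bin_freqs) / (right - center)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
    return fb


def filter_center_frequencies(cfg: MfccConfig) -> np.ndarray:
    """Center (apex) frequency of each filter, in Hz."""
    mel_points = np.linspace(hz_to_mel(cfg.fmin_hz), hz_to_mel(cfg.fmax_hz),
                             cfg.n_mels + 2)
    return np.asarray(mel_to_hz(mel_points[1:-1]))


def log_mel(power: np.ndarray, fb: np.ndarray, log_floor: float = 1e-10) -> np.ndarray:
    """L(i) = ln(eps + sum_k |X(k)|^2 H(i,k)), per frame."""
    power = np.asarray(power, dtype=np.float64)
    if power.shape[-1] != fb.shape[1]:
        raise ValueError(
            f"power has {power.shape[-1]} bins but filterbank expects {fb.shape[1]}"
        )
    return np.log(log_floor + power @ fb.T)


def dct_matrix(n_coeffs: int, n_mels: int) -> np.ndarray:
    """(n_coeffs, n_mels) cosine matrix: C[j, i] = cos(pi j (2(i+1) - 1) / (2M)).

    This is the unnormalized DCT-II without the conventional factor of 2,
    so a constant log-mel vector of value c maps to MFCC(0) = M * c and
    MFCC(j > 0) = 0.
    """
    j = np.arange(n_coeffs)[:, None]
    i = np.arange(1, n_mels + 1)[None, :]
    return np.cos(np.pi * j * (2 * i - 1) / (2.0 * n_mels))


def dct_coeffs(L: np.ndarray, n_coeffs: int) -> np.ndarray:
    """First ``n_coeffs`` cepstral coefficients of each frame's log-mel row."""
    L = np.asarray(L, dtype=np.float64)
    n_mels = L.shape[-1]
    if n_coeffs > n_mels:
        raise ValueError("n_coeffs must be <= number of mel filters")
    return L @ dct_matrix(n_coeffs, n_mels).T


def mfcc_pipeline(
    x: np.ndarray, sample_rate_hz: int, cfg: MfccConfig = MfccConfig()
) -> FeatureMatrix:
    """STFT -> mel filterbank -> log -> DCT for one segment."""
    power = stft_power(x, cfg)
    fb = mel_filterbank(cfg, sample_rate_hz)
    values = dct_coeffs(log_mel(power, fb, cfg.log_floor), cfg.n_coeffs)
    times = np.arange(values.shape[0]) * cfg.hop_length * 1000.0 / sample_rate_hz
    return FeatureMatrix(values=values, frame_times_ms=times)


def mfcc_batch(
    segments: np.ndarray, sample_rate_hz: int, cfg: MfccConfig = MfccConfig(),
    chunk: int = 256,
) -> np.ndarray:
    """MFCCs for a stack of equal-length segments: (n, frames, n_coeffs).

    Vectorized over segments in chunks (bounded memory); numerically
    identical to mapping ``mfcc_pipeline`` over rows.
    """
    segments = np.asarray(segments, dtype=np.float64)
    n, n_samples = segments.shape
    count = n_frames(n_samples, cfg)
    idx = np.arange(cfg.n_fft)[None, :] + cfg.hop_length * np.arange(count)[:, None]
    window = np.hamming(cfg.n_fft)
    fb_t = mel_filterbank(cfg, sample_rate_hz).T
    dct_t = dct_matrix(cfg.n_coeffs, cfg.n_mels).T
    out = np.empty((n, count, cfg.n_coeffs))
    for i in range(0, n, chunk):
        frames = segments[i : i + chunk][:, idx] * window
        power = np.abs(np.fft.rfft(frames, axis=2)) ** 2
        out[i : i + chunk] = np.log(cfg.log_floor + power @ fb_t) @ dct_t
    return out
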