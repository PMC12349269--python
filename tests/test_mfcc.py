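"""MFCC chain: mel formula, filterbank geometry, log compression, DCT.

The independent oracle re-derives the whole chain naively: explicit
O(N^2) DFT matrix per frame, per-bin triangle evaluation, and a
double-loop DCT, sharing no code with the pipeline under test.
"""

import numpy as np
import pytest

from bowelsound.mfcc import (
    MfccConfig,
    dct_coeffs,
    filter_center_frequencies,
    frame_signal,
    hz_to_mel,
    log_mel,
    mel_filterbank,
    mel_to_hz,
    mfcc_batch,
    mfcc_pipeline,
    n_frames,
    stft_power,
)

CFG = MfccConfig()
SR = 44100
SEG_SAMPLES = 16537  # 375 ms at 44.1 kHz


# ---------------------------------------------------------------------------
# naive reference implementation (oracle)

def naive_mfcc(x, sr, cfg=CFG):
    N = cfg.n_fft
    w = np.hamming(N)
    n = np.arange(N)
    k = np.arange(N // 2 + 1)
    dft = np.exp(-2j * np.pi * k[:, None] * n[None, :] / N)  # explicit DFT matrix
    starts = range(0, len(x) - N + 1, cfg.hop_length)
    power = np.array([np.abs(dft @ (x[s : s + N] * w)) ** 2 for s in starts])

    # explicit triangular filters evaluated per bin
    mel_pts = np.linspace(2595 * np.log10(1 + cfg.fmin_hz / 700),
                          2595 * np.log10(1 + cfg.fmax_hz / 700), cfg.n_mels + 2)
    hz_pts = 700 * (10 ** (mel_pts / 2595) - 1)
    bins = k * sr / N
    H = np.zeros((cfg.n_mels, len(bins)))
    for i in range(cfg.n_mels):
        lo, c, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        for b, f in enumerate(bins):
            if lo < f <= c:
                H[i, b] = (f - lo) / (c - lo)
            elif c < f < hi:
                H[i, b] = (hi - f) / (hi - c)

    L = np.log(cfg.log_floor + power @ H.T)

    out = np.zeros((L.shape[0], cfg.n_coeffs))
    for t in range(L.shape[0]):
        for j in range(cfg.n_coeffs):
            acc = 0.0
            for i in range(1, cfg.n_mels + 1):
                acc += L[t, i - 1] * np.cos(np.pi * j * (2 * i - 1) / (2 * cfg.n_mels))
            out[t, j] = acc
    return out


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert hz_to_mel(0.0) == 0.0

    def test_700hz_reference_point(self):
        assert hz_to_mel(700.0) == pytest.approx(2595 * np.log10(2), abs=1e-9)

    @pytest.mark.parametrize("f", [50.0, 1000.0, 5000.0])
    def test_inverse_roundtrip(self, f):
        assert mel_to_hz(hz_to_mel(f)) == pytest.approx(f, rel=1e-9)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)


class TestStft:
    def test_zero_segment_zero_power(self):
        power = stft_power(np.zeros(SEG_SAMPLES), CFG)
        assert power.shape == (31, 513)
        assert np.all(power == 0.0)

    def test_frame_count_for_default_segment(self):
        assert n_frames(SEG_SAMPLES, CFG) == 31  # 1 + floor((16537-1024)/512)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            stft_power(np.zeros(1000), CFG)

    def test_bin_frequency_sinusoid_peaks_at_its_bin(self):
        k0 = 37
        t = np.arange(SEG_SAMPLES)
        x = np.sin(2 * np.pi * k0 * t / CFG.n_fft)
        power = stft_power(x, CFG)
        assert np.all(power.argmax(axis=1) == k0)

    def test_framing_matches_manual_slices(self):
        x = np.arange(3000, dtype=float)
        frames = frame_signal(x, MfccConfig(n_fft=1024, hop_length=512))
        assert frames.shape == (4, 1024)
        assert np.array_equal(frames[2], x[1024 : 2048])


class TestFilterbank:
    def test_every_filter_nonempty(self):
        fb = mel_filterbank(CFG, SR)
        assert fb.shape == (32, 513)
        assert np.all(fb.sum(axis=1) > 0)
        assert np.all(fb >= 0)

    def test_centers_equally_spaced_in_mel(self):
        centers = filter_center_frequencies(CFG)
        mels = np.asarray(hz_to_mel(centers))
        diffs = np.diff(mels)
        assert np.all(np.diff(centers) > 0)
        assert np.allclose(diffs, diffs[0], atol=1e-6)

    def test_row_maximum_sits_at_the_apex(self):
        fb = mel_filterbank(CFG, SR)
        centers = filter_center_frequencies(CFG)
        bin_freqs = np.arange(513) * SR / CFG.n_fft
        bin_width = SR / CFG.n_fft
        for i in range(32):
            # the apex value 1 bounds the row; the best bin lies within
            # one bin of the apex frequency
            assert fb[i].max() <= 1.0
            assert abs(bin_freqs[fb[i].argmax()] - centers[i]) < bin_width

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            mel_filterbank(MfccConfig(fmax_hz=9000), 16000)


class TestLogMel:
    def test_zero_power_hits_floor(self):
        fb = mel_filterbank(CFG, SR)
        L = log_mel(np.zeros((3, 513)), fb, 1e-10)
        assert np.allclose(L, np.log(1e-10))

    def test_amplitude_doubling_adds_log4(self, rng):
        x = rng.standard_normal(SEG_SAMPLES) * 0.2
        fb = mel_filterbank(CFG, SR)
        L1 = log_mel(stft_power(x, CFG), fb)
        L2 = log_mel(stft_power(2 * x, CFG), fb)
        assert np.allclose(L2 - L1, np.log(4.0), atol=1e-6)

    def test_hand_computed_two_filters_three_bins(self):
        power = np.array([[1.0, 2.0, 3.0]])
        H = np.array([[0.5, 1.0, 0.0], [0.0, 0.25, 1.0]])
        eps = 1e-10
        want = np.log(eps + np.array([[0.5 + 2.0, 0.5 + 3.0]]))
        assert np.allclose(log_mel(power, H, eps), want, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_mel(np.zeros((2, 10)), np.zeros((5, 11)))


class TestDct:
    def test_constant_input_concentrates_in_coefficient_zero(self):
        c = 1.7
        L = np.full((4, 32), c)
        out = dct_coeffs(L, 13)
        assert np.allclose(out[:, 0], 32 * c, atol=1e-9)
        assert np.allclose(out[:, 1:], 0.0, atol=1e-9)

    def test_coefficient_zero_is_summed_log_mel(self, rng):
        L = rng.standard_normal((5, 32))
        out = dct_coeffs(L, 13)
        assert np.allclose(out[:, 0], L.sum(axis=1), atol=1e-9)

    def test_double_loop_oracle_equivalence(self, rng):
        L = rng.standard_normal((6, 32))
        fast = dct_coeffs(L, 13)
        slow = np.zeros_like(fast)
        for t in range(6):
            for j in range(13):
                for i in range(1, 33):
                    slow[t, j] += L[t, i - 1] * np.cos(np.pi * j * (2 * i - 1) / 64)
        assert np.allclose(fast, slow, atol=1e-9)

    def test_too_many_coefficients_rejected(self):
        with pytest.raises(ValueError):
            dct_coeffs(np.zeros((2, 8)), 9)


class TestPipeline:
    def test_default_segment_shape(self, rng):
        x = rng.standard_normal(SEG_SAMPLES) * 0.1
        fm = mfcc_pipeline(x, SR, CFG)
        assert fm.shape == (31, 13)
        assert np.all(np.isfinite(fm.values))

    def test_hop_shift_shifts_frames(self, rng):
        long = rng.standard_normal(SEG_SAMPLES + CFG.hop_length) * 0.1
        a = mfcc_pipeline(long[: SEG_SAMPLES], SR, CFG).values
        b = mfcc_pipeline(long[CFG.hop_length :], SR, CFG).values
        assert np.allclose(a[1:], b[:-1], atol=1e-6)

    def test_determinism(self, rng):
        x = rng.standard_normal(SEG_SAMPLES) * 0.1
        assert np.array_equal(mfcc_pipeline(x, SR, CFG).values,
                              mfcc_pipeline(x.copy(), SR, CFG).values)

    def test_batch_matches_single(self, rng):
        xs = rng.standard_normal((3, SEG_SAMPLES)) * 0.1
        batch = mfcc_batch(xs, SR, CFG)
        for i in range(3):
            assert np.allclose(batch[i], mfcc_pipeline(xs[i], SR, CFG).values,
                               atol=1e-12)

    def test_naive_oracle_equivalence_sample(self, rng):
        """Spot equivalence on a handful of segments; the acceptance suite
        repeats this at 100 segments."""
        for _ in range(5):
            x = rng.standard_normal(SEG_SAMPLES) * 0.3
            got = mfcc_pipeline(x, SR, CFG).values
            want = naive_mfcc(x, SR, CFG)
            assert np.max(np.abs(got - want)) < 1e-6

    def test_finite_for_silent_input(self):
        fm = mfcc_pipeline(np.zeros(SEG_SAMPLES), SR, CFG)
        assert np.all(np.isfinite(fm.values))
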