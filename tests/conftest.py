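import numpy as np
import pytest

from bowelsound.audio import AudioRecording
from bowelsound.model import BowelSoundClassifier, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """A small but structurally complete model, cheap enough for unit tests."""
    return ModelConfig(conv_filters=6, n_blocks=2, n_heads=2, d_model=8,
                       ffn_dim=10, dense_hidden=5, dropout=0.0,
                       input_shape=(7, 4), seed=3)


@pytest.fixture
def tiny_model(tiny_model_config):
    return BowelSoundClassifier(tiny_model_config)


def make_tone(freq_hz: float, duration_s: float, sr: int = 8000,
              amplitude: float = 0.5) -> AudioRecording:
    t = np.arange(int(duration_s * sr)) / sr
    return AudioRecording(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                          sample_rate_hz=sr)


def make_noise(duration_s: float, sr: int = 8000, seed: int = 0,
               amplitude: float = 0.3) -> AudioRecording:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(duration_s * sr))
    x = amplitude * x / np.max(np.abs(x))
    return AudioRecording(samples=x, sample_rate_hz=sr)
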