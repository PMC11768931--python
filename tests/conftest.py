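import numpy as np
import pytest

from callernet.audio import AudioClip
from callernet.synthetic import SyntheticDatasetConfig, default_specs, generate_clips


def fft_peak_hz(x: np.ndarray, sample_rate: int) -> float:
    """Frequency of the strongest FFT bin — shared oracle for pitch checks."""
    freqs = np.fft.rfftfreq(len(x), 1.0 / sample_rate)
    return float(freqs[np.argmax(np.abs(np.fft.rfft(x)))])


def spectral_centroid_hz(x: np.ndarray, sample_rate: int) -> float:
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1.0 / sample_rate)
    return float((freqs * mag).sum() / mag.sum())


def sine_clip(f0: float, duration_s: float = 2.0, sample_rate: int = 16_000,
              amplitude: float = 0.5) -> AudioClip:
    t = np.arange(round(duration_s * sample_rate)) / sample_rate
    return AudioClip(amplitude * np.sin(2 * np.pi * f0 * t), sample_rate)


@pytest.fixture(scope="session")
def small_call_clips():
    """Short reduced-rate calls of each class, reused across tests."""
    cfg = SyntheticDatasetConfig(
        per_class_counts={"roar": 4, "rumble": 4, "trumpet": 4},
        specs=default_specs(duration_s=1.0, sample_rate=8000), seed=11)
    return generate_clips(cfg)
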