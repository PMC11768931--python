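"""Spectrogram-pipeline features: MFCC and chroma constant-Q profiles.

Both features share one framing convention — Hann window of ``frame_length``
samples, no padding, ``n_frames = 1 + (len - frame_length) // hop`` — so a
clip's MFCC and chroma matrices always align frame-for-frame. Feature
extraction is deterministic (no RNG anywhere).

The stacked image is (n_mfcc + 12) rows by n_frames columns; per-row
z-normalization statistics are fitted on the training split only and applied
unchanged elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from .audio import AudioClip, ValidationError

C1_HZ = 32.70319566257483  # pitch C1; chroma bin 0 = C
LOG_FLOOR = 1e-10


@dataclass
class FeatureConfig:
    n_mfcc: int = 13
    frame_length: int = 2048
    hop_length: int = 512
    n_mels: int = 128
    chroma_octaves: int = 7

    @property
    def n_rows(self) -> int:
        return self.n_mfcc + 12


@dataclass
class FeatureImage:
    mfcc: np.ndarray
    chroma_cqt: np.ndarray
    label: str | None = None

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.mfcc, self.chroma_cqt])


def frame_count(n_samples: int, frame_length: int, hop_length: int) -> int:
    if n_samples < frame_length:
        raise ValidationError(
            f"clip of {n_samples} samples is shorter than one {frame_length}-sample frame")
    return 1 + (n_samples - frame_length) // hop_length


def _frames(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    n = frame_count(len(x), frame_length, hop_length)
    idx = np.arange(frame_length)[None, :] + hop_length * np.arange(n)[:, None]
    return x[idx]


def _power_spectrum(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    frames = _frames(x.astype(np.float64), frame_length, hop_length)
    window = np.hanning(frame_length)
    spec = rfft(frames * window, axis=1)
    return (np.abs(spec) ** 2).T  # (bins, frames)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filters (n_mels x n_fft//2+1), peak-normalized."""
    fmax = fmax or sample_rate / 2.0
    freqs = np.linspace(0, sample_rate / 2.0, n_fft // 2 + 1)
    mel_pts = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, ctr, hi = mel_pts[i], mel_pts[i + 1], mel_pts[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def compute_mfcc(clip: AudioClip, n_mfcc: int = 13, frame_length: int = 2048,
                 hop_length: int = 512, n_mels: int = 128) -> np.ndarray:
    """Mel-frequency cepstral coefficients, (n_mfcc x n_frames).

    Power is floored at 1e-10 before the log, so silent input gives constant
    finite columns.
    """
    if n_mfcc < 1:
        raise ValidationError("n_mfcc must be >= 1")
    power = _power_spectrum(clip.samples, frame_length, hop_length)
    fb = mel_filterbank(clip.sample_rate, frame_length, n_mels)
    logmel = 10.0 * np.log10(np.maximum(fb @ power, LOG_FLOOR))
    coeffs = dct(logmel, type=2, axis=0, norm="ortho")[:n_mfcc]
    return np.ascontiguousarray(coeffs, dtype=np.float32)


def chroma_filterbank(sample_rate: int, n_fft: int, fmin: float = C1_HZ,
                      n_octaves: int = 7) -> np.ndarray:
    """Fold log-spaced semitone filters into 12 pitch classes (row 0 = C)."""
    freqs = np.linspace(0, sample_rate / 2.0, n_fft // 2 + 1)
    fb = np.zeros((12, len(freqs)))
    n_bins = 12 * n_octaves
    for k in range(n_bins):
        ctr = fmin * 2.0 ** (k / 12.0)
        if ctr >= sample_rate / 2.0:
            break
        lo, hi = ctr * 2.0 ** (-1 / 12.0), ctr * 2.0 ** (1 / 12.0)
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[k % 12] += np.clip(np.minimum(up, down), 0.0, None)
    return fb


def compute_chroma_cqt(clip: AudioClip, hop_length: int = 512,
                       frame_length: int = 2048, fmin: float = C1_HZ,
                       n_octaves: int = 7) -> np.ndarray:
    """12 x n_frames pitch-class energy profile; columns normalized to max 1.

    Zero-energy columns fall back to uniform 1/12 (never NaN).
    """
    if fmin >= clip.sample_rate / 2.0:
        raise ValidationError("sample rate too low for the requested CQT minimum frequency")
    power = _power_spectrum(clip.samples, frame_length, hop_length)
    fb = chroma_filterbank(clip.sample_rate, frame_length, fmin, n_octaves)
    chroma = fb @ power
    peaks = chroma.max(axis=0)
    out = np.full_like(chroma, 1.0 / 12.0)
    nz = peaks > 0
    out[:, nz] = chroma[:, nz] / peaks[nz]
    return np.ascontiguousarray(out, dtype=np.float32)


def build_feature_image(clip: AudioClip, config: FeatureConfig | None = None,
                        normalizer: "FeatureNormalizer | None" = None) -> FeatureImage:
    """MFCC stacked over chroma for one clip, optionally z-normalized."""
    cfg = config or FeatureConfig()
    mfcc = compute_mfcc(clip, cfg.n_mfcc, cfg.frame_length, cfg.hop_length, cfg.n_mels)
    chroma = compute_chroma_cqt(clip, cfg.hop_length, cfg.frame_length,
                                n_octaves=cfg.chroma_octaves)
    if mfcc.shape[1] != chroma.shape[1]:
        raise RuntimeError("internal error: feature frame counts diverged")
    img = FeatureImage(mfcc=mfcc, chroma_cqt=chroma, label=clip.label)
    if normalizer is not None:
        return normalizer.transform(img)
    return img


class FeatureNormalizer:
    """Per-row z-normalization fitted on training images only."""

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, images: list[FeatureImage]) -> "FeatureNormalizer":
        if not images:
            raise ValidationError("cannot fit a normalizer on an empty training set")
        data = np.concatenate([img.stacked.astype(np.float64) for img in images], axis=1)
        self.mean_ = data.mean(axis=1, keepdims=True)
        self.std_ = data.std(axis=1, keepdims=True)
        self.std_[self.std_ == 0] = 1.0
        return self

    def transform(self, img: FeatureImage) -> FeatureImage:
        if self.mean_ is None:
            raise ValidationError("normalizer is not fitted")
        z = ((img.stacked.astype(np.float64) - self.mean_) / self.std_).astype(np.float32)
        n_mfcc = img.mfcc.shape[0]
        return FeatureImage(mfcc=z[:n_mfcc], chroma_cqt=z[n_mfcc:], label=img.label)
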