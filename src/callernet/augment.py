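"""Waveform augmentation operators and the two dataset-expansion regimes.

Operators: phase-vocoder time stretching (pitch-preserving), pitch shifting
(stretch + resample, duration-preserving), their combination, and additive
white Gaussian noise at a requested SNR. Regimes:

* approach 1 (:func:`balance_classes`) — pad every training class with mildly
  augmented copies until the classes are balanced;
* approach 2 (:func:`expand_fourfold`) — each source clip gains exactly four
  augmented variants, one per operator kind, so the output is 5x the input.

Default parameter ranges are mild (stretch 0.8-1.25, pitch within +/-2
semitones, SNR 15-30 dB) so the class identity of low-frequency calls is
preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .audio import AudioClip, ValidationError, load_audio, save_wav, standardize_duration

OP_KINDS = ("time_stretch", "pitch_shift", "combined", "gaussian_noise")

STRETCH_RANGE = (0.8, 1.25)
PITCH_RANGE_SEMITONES = 2.0
SNR_RANGE_DB = (15.0, 30.0)
MAX_PITCH_SHIFT = 12.0


@dataclass(frozen=True)
class AugmentationOp:
    kind: str
    rate: float | None = None
    semitones: float | None = None
    snr_db: float | None = None

    def validate(self) -> None:
        if self.kind not in OP_KINDS:
            raise ValidationError(f"unknown augmentation kind {self.kind!r}")
        if self.kind in ("time_stretch", "combined") and (self.rate is None or self.rate <= 0):
            raise ValidationError("stretch rate must be positive")
        if self.kind in ("pitch_shift", "combined"):
            if self.semitones is None or abs(self.semitones) > MAX_PITCH_SHIFT:
                raise ValidationError(f"pitch shift must be within +/-{MAX_PITCH_SHIFT} semitones")
        if self.kind == "gaussian_noise" and (self.snr_db is None or math.isnan(self.snr_db)):
            raise ValidationError("snr_db must be finite or +inf")

    def describe(self) -> str:
        if self.kind == "time_stretch":
            return f"aug:time_stretch:{self.rate:.3f}"
        if self.kind == "pitch_shift":
            return f"aug:pitch_shift:{self.semitones:+.2f}"
        if self.kind == "combined":
            return f"aug:combined:{self.rate:.3f}:{self.semitones:+.2f}"
        return f"aug:gaussian_noise:{self.snr_db:.1f}dB"


# ---------------------------------------------------------------------------
# Signal operators
# ---------------------------------------------------------------------------

def _stft(y: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    window = np.hanning(n_fft)
    n_frames = 1 + (len(y) - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.fft.rfft(y[idx] * window, axis=1).T  # (bins, frames)


def _istft(spec: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    window = np.hanning(n_fft)
    frames = np.fft.irfft(spec.T, n=n_fft, axis=1)
    n_frames = frames.shape[0]
    out = np.zeros(n_fft + hop * (n_frames - 1))
    norm = np.zeros_like(out)
    for i in range(n_frames):
        out[i * hop:i * hop + n_fft] += frames[i] * window
        norm[i * hop:i * hop + n_fft] += window ** 2
    return out / np.maximum(norm, 1e-8)


def _fft_size(n_samples: int) -> int:
    n_fft = 2048
    while n_fft > n_samples and n_fft > 64:
        n_fft //= 2
    return n_fft


def time_stretch(clip: AudioClip, rate: float) -> AudioClip:
    """Phase-vocoder stretch: duration scales by 1/rate, pitch is preserved."""
    if rate <= 0:
        raise ValidationError("stretch rate must be positive")
    y = clip.samples.astype(np.float64)
    n_out = max(1, round(len(y) / rate))
    if rate == 1.0:
        return clip.with_samples(y)
    n_fft = _fft_size(len(y))
    if len(y) < n_fft:
        raise ValidationError("clip too short to time-stretch")
    hop = n_fft // 4
    spec = _stft(y, n_fft, hop)
    n_bins, n_frames = spec.shape
    steps = np.arange(0, n_frames - 1, rate)
    omega = 2 * np.pi * hop * np.arange(n_bins) / n_fft
    phase = np.angle(spec[:, 0]).copy()
    out = np.empty((n_bins, len(steps)), dtype=complex)
    for i, step in enumerate(steps):
        j = int(step)
        frac = step - j
        mag = (1 - frac) * np.abs(spec[:, j]) + frac * np.abs(spec[:, min(j + 1, n_frames - 1)])
        out[:, i] = mag * np.exp(1j * phase)
        dphi = np.angle(spec[:, min(j + 1, n_frames - 1)]) - np.angle(spec[:, j]) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase += omega + dphi
    y_out = _istft(out, n_fft, hop)
    if len(y_out) >= n_out:
        y_out = y_out[:n_out]
    else:
        y_out = np.pad(y_out, (0, n_out - len(y_out)))
    return clip.with_samples(np.clip(y_out, -1.0, 1.0))


def pitch_shift(clip: AudioClip, semitones: float) -> AudioClip:
    """Shift pitch by 2^(semitones/12); clip duration is preserved exactly."""
    if abs(semitones) > MAX_PITCH_SHIFT:
        raise ValidationError(f"pitch shift must be within +/-{MAX_PITCH_SHIFT} semitones")
    if semitones == 0:
        return clip.with_samples(clip.samples)
    factor = 2.0 ** (semitones / 12.0)
    n = len(clip.samples)
    # stretch to n*factor samples (pitch unchanged), then resample back to n,
    # which compresses the time axis and scales every frequency by `factor`.
    stretched = time_stretch(clip, rate=1.0 / factor)
    frac = Fraction(factor).limit_denominator(1000)
    y = resample_poly(stretched.samples.astype(np.float64), frac.denominator, frac.numerator)
    if len(y) >= n:
        y = y[:n]
    else:
        y = np.pad(y, (0, n - len(y)))
    return clip.with_samples(np.clip(y, -1.0, 1.0))


def add_gaussian_noise(clip: AudioClip, snr_db: float, seed: int = 0) -> AudioClip:
    """Additive white Gaussian noise at an exact measured SNR (pre-clipping)."""
    if math.isnan(snr_db):
        raise ValidationError("snr_db must be finite or +inf")
    if math.isinf(snr_db) and snr_db > 0:
        return clip.with_samples(clip.samples)
    x = clip.samples.astype(np.float64)
    p_signal = float((x ** 2).mean())
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(x))
    noise /= np.sqrt(float((noise ** 2).mean()))
    p_noise = p_signal / (10.0 ** (snr_db / 10.0))
    y = x + noise * np.sqrt(p_noise)
    return clip.with_samples(np.clip(y, -1.0, 1.0))


def apply_op(clip: AudioClip, op: AugmentationOp, seed: int = 0,
             target_s: float | None = None) -> AudioClip:
    """Apply one operator, then re-standardize to the pipeline duration."""
    op.validate()
    if op.kind == "time_stretch":
        out = time_stretch(clip, op.rate)
    elif op.kind == "pitch_shift":
        out = pitch_shift(clip, op.semitones)
    elif op.kind == "combined":
        out = pitch_shift(time_stretch(clip, op.rate), op.semitones)
    else:
        out = add_gaussian_noise(clip, op.snr_db, seed=seed)
    if target_s is None:
        target_s = clip.duration_s
    return standardize_duration(out, target_s, mode="repeat")


def sample_balance_op(rng: np.random.Generator,
                      kinds: tuple[str, ...] = ("time_stretch", "pitch_shift")) -> AugmentationOp:
    kind = kinds[rng.integers(len(kinds))]
    if kind == "time_stretch":
        return AugmentationOp("time_stretch", rate=float(rng.uniform(*STRETCH_RANGE)))
    if kind == "pitch_shift":
        return AugmentationOp("pitch_shift",
                              semitones=float(rng.uniform(-PITCH_RANGE_SEMITONES,
                                                          PITCH_RANGE_SEMITONES)))
    raise ValidationError(f"balancing supports time_stretch/pitch_shift, got {kind!r}")


def sample_fourfold_ops(rng: np.random.Generator) -> list[AugmentationOp]:
    """One op of each kind, with randomized parameters."""
    return [
        AugmentationOp("time_stretch", rate=float(rng.uniform(*STRETCH_RANGE))),
        AugmentationOp("pitch_shift",
                       semitones=float(rng.uniform(-PITCH_RANGE_SEMITONES,
                                                   PITCH_RANGE_SEMITONES))),
        AugmentationOp("combined", rate=float(rng.uniform(*STRETCH_RANGE)),
                       semitones=float(rng.uniform(-PITCH_RANGE_SEMITONES,
                                                   PITCH_RANGE_SEMITONES))),
        AugmentationOp("gaussian_noise", snr_db=float(rng.uniform(*SNR_RANGE_DB))),
    ]


# ---------------------------------------------------------------------------
# Manifest-level regimes
# ---------------------------------------------------------------------------

def _guard_no_test(manifest: pd.DataFrame) -> None:
    if "split" in manifest.columns and (manifest["split"] == "test").any():
        raise ValidationError("augmentation must never touch the test split")


def _augment_row(row, op: AugmentationOp, out_dir: Path, tag: str, seed: int) -> dict:
    clip = load_audio(row["path"], label=row["label"])
    aug = apply_op(clip, op, seed=seed)
    clip_id = f"{row['clip_id']}_{tag}"
    path = out_dir / f"{clip_id}.wav"
    save_wav(aug, path)
    new = dict(row)
    new.update(clip_id=clip_id, path=str(path), provenance=op.describe())
    return new


def balanced_target(class_counts: dict[str, int], round_to: int = 10) -> int:
    """Approach-1 target: largest class rounded up to a multiple of 10."""
    top = max(class_counts.values())
    return math.ceil(top / round_to) * round_to


def balance_classes(manifest: pd.DataFrame, target_per_class: int | None = None,
                    ops: tuple[str, ...] = ("time_stretch", "pitch_shift"),
                    seed: int = 0, out_dir=None) -> pd.DataFrame:
    """Pad every class with augmented copies until it has exactly
    ``target_per_class`` clips; originals are kept untouched."""
    _guard_no_test(manifest)
    counts = manifest["label"].value_counts().to_dict()
    if target_per_class is None:
        target_per_class = balanced_target(counts)
    if counts and target_per_class < max(counts.values()):
        raise ValidationError(
            f"target {target_per_class} is below the largest class ({max(counts.values())})")
    out_dir = Path(out_dir) if out_dir is not None else Path(manifest["path"].iloc[0]).parent / "augmented"
    rng = np.random.default_rng(seed)
    new_rows = []
    for label in sorted(counts):
        rows = manifest.loc[manifest["label"] == label]
        need = target_per_class - len(rows)
        for i in range(need):
            src = rows.iloc[int(rng.integers(len(rows)))]
            op = sample_balance_op(rng, ops)
            sub_seed = int(rng.integers(2 ** 31))
            new_rows.append(_augment_row(src, op, out_dir, f"bal{i:03d}", sub_seed))
    out = pd.concat([manifest, pd.DataFrame(new_rows, columns=manifest.columns)],
                    ignore_index=True) if new_rows else manifest.copy()
    return out


def expand_fourfold(manifest: pd.DataFrame, seed: int = 0, out_dir=None) -> pd.DataFrame:
    """Approach 2: original + one variant per op kind = 5x the input rows."""
    _guard_no_test(manifest)
    if len(manifest) == 0:
        return manifest.copy()
    out_dir = Path(out_dir) if out_dir is not None else Path(manifest["path"].iloc[0]).parent / "augmented"
    rng = np.random.default_rng(seed)
    new_rows = []
    for _, row in manifest.iterrows():
        for op in sample_fourfold_ops(rng):
            sub_seed = int(rng.integers(2 ** 31))
            new_rows.append(_augment_row(row, op, out_dir, op.kind, sub_seed))
    return pd.concat([manifest, pd.DataFrame(new_rows, columns=manifest.columns)],
                     ignore_index=True)


# In-memory variants used by the comparison harness -------------------------

def balance_clips(clips: list[AudioClip], target_per_class: int | None = None,
                  seed: int = 0) -> list[AudioClip]:
    counts: dict[str, int] = {}
    for c in clips:
        counts[c.label] = counts.get(c.label, 0) + 1
    if target_per_class is None:
        target_per_class = balanced_target(counts)
    if counts and target_per_class < max(counts.values()):
        raise ValidationError("target below largest class size")
    rng = np.random.default_rng(seed)
    out = list(clips)
    for label in sorted(counts):
        members = [c for c in clips if c.label == label]
        for _ in range(target_per_class - len(members)):
            src = members[int(rng.integers(len(members)))]
            op = sample_balance_op(rng)
            out.append(apply_op(src, op, seed=int(rng.integers(2 ** 31))))
    return out


def expand_clips_fourfold(clips: list[AudioClip], seed: int = 0) -> list[AudioClip]:
    rng = np.random.default_rng(seed)
    out = list(clips)
    for clip in clips:
        for op in sample_fourfold_ops(rng):
            out.append(apply_op(clip, op, seed=int(rng.integers(2 ** 31))))
    return out
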