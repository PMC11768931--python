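"""Audio I/O, clip standardization, silence trimming and stratified splits.

Clips are plain mono float32 waveforms in [-1, 1]. WAV files are PCM-16
(24-bit and float WAVs are accepted on read). All durations are seconds;
sample indexing is 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

MANIFEST_COLUMNS = ["clip_id", "path", "label", "split", "provenance"]


class AudioIOError(IOError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and optional class label."""

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    clip_id: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D mono waveform")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioClip":
        return replace(self, samples=np.asarray(samples, dtype=np.float32))


def save_wav(clip: AudioClip, path) -> None:
    """Write PCM 16-bit mono WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = np.clip(clip.samples, -1.0, 1.0).astype(np.float64)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, clip.sample_rate, pcm)


def load_audio(path, target_rate: int | None = None, label: str | None = None,
               clip_id: str | None = None) -> AudioClip:
    """Read a WAV file to a mono float clip, resampling to ``target_rate``.

    Multichannel audio is averaged across channels. Integer PCM is scaled to
    [-1, 1]; float data is used as-is.
    """
    path = Path(path)
    if not path.exists():
        raise AudioIOError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - surface decoding problems with the path
        raise AudioIOError(f"cannot decode audio file {path}: {exc}") from exc
    if data.dtype == np.int16:
        x = data.astype(np.float32) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float32) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float32) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float32)
    else:
        raise AudioIOError(f"unsupported WAV encoding {data.dtype} in {path}")
    if x.ndim == 2:
        x = x.mean(axis=1)
    clip = AudioClip(x, rate, label=label, clip_id=clip_id or path.stem)
    if target_rate is not None and target_rate != rate:
        clip = resample(clip, target_rate)
    return clip


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    frac = Fraction(target_rate, clip.sample_rate)
    y = resample_poly(clip.samples.astype(np.float64), frac.numerator, frac.denominator)
    return AudioClip(np.clip(y, -1.0, 1.0), target_rate,
                     label=clip.label, clip_id=clip.clip_id)


def standardize_duration(clip: AudioClip, target_s: float, mode: str = "pad") -> AudioClip:
    """Force a clip to exactly round(target_s * rate) samples.

    ``pad`` appends zeros, ``truncate`` keeps the leading segment, ``repeat``
    tiles the waveform and truncates. Longer clips are always truncated.
    """
    if target_s <= 0:
        raise ValidationError("target duration must be positive")
    if mode not in ("pad", "truncate", "repeat"):
        raise ValidationError(f"unknown standardization mode {mode!r}")
    n_target = round(target_s * clip.sample_rate)
    x = clip.samples
    if len(x) >= n_target:
        return clip.with_samples(x[:n_target])
    if mode == "pad" or len(x) == 0:
        out = np.zeros(n_target, dtype=np.float32)
        out[:len(x)] = x
    elif mode == "truncate":
        out = np.zeros(n_target, dtype=np.float32)
        out[:len(x)] = x
    else:  # repeat
        reps = math.ceil(n_target / len(x))
        out = np.tile(x, reps)[:n_target]
    return clip.with_samples(out)


def trim_silence(clip: AudioClip, threshold_db: float = -40.0,
                 frame_ms: float = 25.0, hop_ms: float = 10.0) -> AudioClip:
    """Strip leading/trailing frames quieter than ``threshold_db`` re peak RMS.

    Falls back to the original clip when every frame is below threshold, so
    the result is never empty.
    """
    if threshold_db >= 0:
        raise ValidationError("threshold_db must be negative (relative to peak)")
    x = clip.samples
    frame = max(1, round(frame_ms * 1e-3 * clip.sample_rate))
    hop = max(1, round(hop_ms * 1e-3 * clip.sample_rate))
    if len(x) <= frame:
        return clip
    n_frames = 1 + (len(x) - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    rms = np.sqrt((x[idx].astype(np.float64) ** 2).mean(axis=1))
    peak = rms.max()
    if peak <= 0:
        return clip
    loud = 20.0 * np.log10(rms / peak + 1e-20) >= threshold_db
    if not loud.any():
        return clip
    first, last = np.flatnonzero(loud)[[0, -1]]
    start = first * hop
    end = len(x) if last == n_frames - 1 else last * hop + frame
    return clip.with_samples(x[start:end])


# ---------------------------------------------------------------------------
# Manifests and stratified splitting
# ---------------------------------------------------------------------------

def empty_manifest() -> pd.DataFrame:
    return pd.DataFrame(columns=MANIFEST_COLUMNS)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"clip_id": str, "path": str, "label": str,
                                  "split": str, "provenance": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def split_counts(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Deterministic per-class split sizes.

    Train takes floor(r_train * n); validation takes the larger share of the
    remainder (ceil), test the rest. For 80:10:10 this yields 77 -> (61, 8, 8),
    95 -> (76, 10, 9) and 63 -> (50, 7, 6).
    """
    rt, rv, rte = ratios
    n_train = math.floor(rt * n)
    rem = n - n_train
    n_val = math.ceil(rem * rv / (rv + rte) - 1e-9)  # guard float noise at exact halves
    return n_train, n_val, rem - n_val


@dataclass
class SplitAssignment:
    ratios: tuple[float, float, float]
    per_class_counts: dict[str, tuple[int, int, int]]
    assignment: dict[str, str]
    seed: int = 0


def stratified_split(manifest: pd.DataFrame,
                     ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitAssignment:
    """Assign each clip to train/val/test, stratified per class.

    Membership is randomized by ``seed``; the per-class counts follow
    :func:`split_counts` and are seed-independent.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError("ratios must be positive and sum to 1")
    labels = manifest["label"]
    bad = manifest.loc[labels.isna() | (labels.astype(str).str.len() == 0), "clip_id"]
    if len(bad):
        raise ValidationError(f"unlabelled clips: {sorted(bad.tolist())}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    per_class: dict[str, tuple[int, int, int]] = {}
    for label in sorted(manifest["label"].unique()):
        ids = manifest.loc[manifest["label"] == label, "clip_id"].tolist()
        n_train, n_val, n_test = split_counts(len(ids), ratios)
        per_class[label] = (n_train, n_val, n_test)
        order = rng.permutation(len(ids))
        for rank, i in enumerate(order):
            tag = ("train" if rank < n_train
                   else "val" if rank < n_train + n_val else "test")
            assignment[str(ids[i])] = tag
    return SplitAssignment(ratios=ratios, per_class_counts=per_class,
                           assignment=assignment, seed=seed)


def apply_split(manifest: pd.DataFrame, split: SplitAssignment) -> pd.DataFrame:
    out = manifest.copy()
    out["split"] = out["clip_id"].astype(str).map(split.assignment)
    return out
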