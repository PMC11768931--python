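"""Synthetic elephant-like calls for the three target classes.

Each call is a band-limited harmonic stack (fundamental drawn from a
class-specific range, 1/h harmonic roll-off, random phases) mixed with white
noise at a configurable power share, then amplitude-modulated. The defaults
emulate the qualitative acoustics of the call types:

* rumble — very low fundamental (10-35 Hz), rich harmonics, little noise,
  slow amplitude modulation;
* roar — low fundamental (60-150 Hz) but noise-dominated and strongly
  modulated;
* trumpet — high, bright fundamental (300-800 Hz), many harmonics, fast
  modulation.

These are acoustic stand-ins that make the classes separable, not faithful
elephant synthesis. Harmonics that would exceed 95% of the Nyquist frequency
are dropped (band-limited additive synthesis), so a spec remains usable at
reduced sample rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioClip, ValidationError, save_wav, write_manifest

LABELS = ("roar", "rumble", "trumpet")

# Composition of the curated call collection this toolkit emulates.
DEFAULT_COUNTS = {"roar": 77, "rumble": 95, "trumpet": 63}

AM_DEPTH = 0.5
PEAK = 0.9
NYQUIST_FRACTION = 0.95


@dataclass(frozen=True)
class CallSpec:
    """Acoustic recipe for one call class."""

    label: str
    f0_range: tuple[float, float]
    n_harmonics: int
    noise_fraction: float
    am_rate_range: tuple[float, float]
    duration_s: float = 6.0
    sample_rate: int = 16_000

    def validate(self) -> None:
        lo, hi = self.f0_range
        nyq = self.sample_rate / 2.0
        if not (0 < lo < hi):
            raise ValidationError(f"f0_range must satisfy 0 < low < high, got {self.f0_range}")
        if hi >= NYQUIST_FRACTION * nyq:
            raise ValidationError(
                f"f0_range high {hi} Hz does not fit below the Nyquist limit at "
                f"{self.sample_rate} Hz")
        if self.n_harmonics < 1:
            raise ValidationError("n_harmonics must be a positive integer")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValidationError(f"noise_fraction must be in [0,1], got {self.noise_fraction}")
        a, b = self.am_rate_range
        if not (0 <= a <= b):
            raise ValidationError(f"am_rate_range must be ordered and non-negative, got {self.am_rate_range}")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")


def default_specs(duration_s: float = 6.0, sample_rate: int = 16_000) -> dict[str, CallSpec]:
    """Class recipes; rumble sits far below trumpet in fundamental frequency."""
    return {
        "rumble": CallSpec("rumble", (10.0, 35.0), 6, 0.10, (1.0, 3.0),
                           duration_s, sample_rate),
        "trumpet": CallSpec("trumpet", (300.0, 800.0), 8, 0.15, (4.0, 8.0),
                            duration_s, sample_rate),
        "roar": CallSpec("roar", (60.0, 150.0), 3, 0.60, (8.0, 15.0),
                         duration_s, sample_rate),
    }


@dataclass
class SyntheticDatasetConfig:
    per_class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    specs: dict[str, CallSpec] = field(default_factory=default_specs)
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        for label, n in self.per_class_counts.items():
            if n < 0:
                raise ValidationError(f"count for {label!r} must be >= 0")
            if n > 0 and label not in self.specs:
                raise ValidationError(f"no CallSpec for label {label!r}")
        for spec in self.specs.values():
            spec.validate()


def generate_call(spec: CallSpec, seed: int) -> AudioClip:
    """Synthesize one call; bit-identical for a given (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = round(spec.duration_s * spec.sample_rate)
    t = np.arange(n, dtype=np.float64) / spec.sample_rate
    f0 = rng.uniform(*spec.f0_range)

    nyq_cap = NYQUIST_FRACTION * spec.sample_rate / 2.0
    harm = np.zeros(n, dtype=np.float64)
    for h in range(1, spec.n_harmonics + 1):
        phase = rng.uniform(0, 2 * np.pi)
        if h * f0 >= nyq_cap:
            continue  # band-limit: aliasing harmonics are dropped
        harm += np.sin(2 * np.pi * h * f0 * t + phase) / h
    p_harm = float((harm ** 2).mean())
    if p_harm > 0:
        harm /= np.sqrt(p_harm)

    noise = rng.standard_normal(n)
    noise /= np.sqrt(float((noise ** 2).mean()))

    nf = spec.noise_fraction
    x = np.sqrt(1.0 - nf) * harm + np.sqrt(nf) * noise

    am_rate = rng.uniform(*spec.am_rate_range)
    am_phase = rng.uniform(0, 2 * np.pi)
    x *= 1.0 + AM_DEPTH * np.sin(2 * np.pi * am_rate * t + am_phase)

    peak = float(np.abs(x).max())
    if peak > 0:
        x *= PEAK / peak
    return AudioClip(x.astype(np.float32), spec.sample_rate, label=spec.label)


def _clip_seed(master_seed: int, class_index: int, clip_index: int) -> int:
    # Counter-based sub-seeds: adding clips never perturbs earlier clips.
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(class_index, clip_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_clips(config: SyntheticDatasetConfig) -> list[AudioClip]:
    """All clips of the configured dataset, in manifest order, in memory."""
    config.validate()
    clips: list[AudioClip] = []
    for ci, label in enumerate(sorted(config.per_class_counts)):
        spec = config.specs.get(label)
        for ki in range(config.per_class_counts[label]):
            clip = generate_call(spec, _clip_seed(config.seed, ci, ki))
            clip = replace(clip, clip_id=f"{label}_{ki:04d}")
            clips.append(clip)
    return clips


def generate_dataset(config: SyntheticDatasetConfig) -> pd.DataFrame:
    """Write one WAV per clip plus a manifest CSV; return the manifest.

    Manifest columns: clip_id, path, label, split (empty), provenance
    ('original'). Per-class counts match the config exactly.
    """
    config.validate()
    if config.output_dir is None:
        raise ValidationError("output_dir is required to write a dataset")
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    rows = []
    for clip in generate_clips(config):
        path = out / f"{clip.clip_id}.wav"
        save_wav(clip, path)
        rows.append({"clip_id": clip.clip_id, "path": str(path),
                     "label": clip.label, "split": "", "provenance": "original"})
    manifest = pd.DataFrame(rows, columns=["clip_id", "path", "label", "split", "provenance"])
    write_manifest(manifest, out / "manifest.csv")
    return manifest
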