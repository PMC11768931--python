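"""Augmentation operators and the two expansion regimes."""

import numpy as np
import pandas as pd
import pytest

from callernet.audio import ValidationError, apply_split, stratified_split
from callernet.augment import (
    add_gaussian_noise, apply_op, AugmentationOp, balance_classes,
    balanced_target, expand_clips_fourfold, expand_fourfold, pitch_shift,
    time_stretch,
)
from callernet.synthetic import SyntheticDatasetConfig, default_specs, generate_dataset
from conftest import fft_peak_hz, sine_clip


def test_time_stretch_changes_length_not_pitch():
    clip = sine_clip(100.0, duration_s=6.0)
    out = time_stretch(clip, 2.0)
    assert abs(len(out.samples) - len(clip.samples) / 2) <= 512  # one hop
    ident = time_stretch(clip, 1.0)
    assert len(ident.samples) == len(clip.samples)
    slow = time_stretch(clip, 1.2)
    peak = fft_peak_hz(slow.samples, clip.sample_rate)
    assert 97.0 <= peak <= 103.0


def test_time_stretch_rejects_nonpositive_rate():
    with pytest.raises(ValidationError):
        time_stretch(sine_clip(100.0), 0.0)


@pytest.mark.parametrize("f0,semitones,expected", [
    (100.0, 12, 200.0), (400.0, -12, 200.0), (220.0, 0, 220.0),
])
def test_pitch_shift_scales_dominant_frequency(f0, semitones, expected):
    clip = sine_clip(f0)
    out = pitch_shift(clip, semitones)
    assert len(out.samples) == len(clip.samples)  # duration preserved exactly
    peak = fft_peak_hz(out.samples, clip.sample_rate)
    assert abs(peak - expected) / expected < 0.03


def test_pitch_shift_cap():
    with pytest.raises(ValidationError):
        pitch_shift(sine_clip(100.0), 24)


def test_gaussian_noise_power_and_determinism():
    clip = sine_clip(200.0, amplitude=0.5)
    noisy = add_gaussian_noise(clip, 20.0, seed=3)
    noise = noisy.samples.astype(np.float64) - clip.samples
    snr = 10 * np.log10((clip.samples.astype(np.float64) ** 2).mean() / (noise ** 2).mean())
    assert abs(snr - 20.0) < 0.5
    same = add_gaussian_noise(clip, 20.0, seed=3)
    assert np.array_equal(noisy.samples, same.samples)
    clean = add_gaussian_noise(clip, np.inf, seed=3)
    assert np.array_equal(clean.samples, clip.samples)


def test_apply_op_restandardizes_duration(small_call_clips):
    clip = small_call_clips[0]
    for op in (AugmentationOp("time_stretch", rate=1.25),
               AugmentationOp("combined", rate=0.9, semitones=1.5),
               AugmentationOp("gaussian_noise", snr_db=25.0)):
        out = apply_op(clip, op, seed=1)
        assert len(out.samples) == len(clip.samples)


@pytest.fixture()
def train_manifest(tmp_path):
    cfg = SyntheticDatasetConfig(
        per_class_counts={"roar": 4, "rumble": 6, "trumpet": 3},
        specs=default_specs(0.5, 8000), seed=2, output_dir=tmp_path)
    manifest = generate_dataset(cfg)
    manifest["split"] = "train"
    return manifest


def test_balance_classes_pads_to_target(train_manifest, tmp_path):
    out = balance_classes(train_manifest, target_per_class=6, seed=0,
                          out_dir=tmp_path / "aug")
    counts = out["label"].value_counts()
    assert set(counts) == {6}
    # originals untouched, new rows carry op provenance
    originals = out[out["provenance"] == "original"]
    pd.testing.assert_frame_equal(
        originals.reset_index(drop=True), train_manifest.reset_index(drop=True))
    added = out[out["provenance"] != "original"]
    assert len(added) == 5 and added["provenance"].str.startswith("aug:").all()


def test_balance_classes_noop_when_balanced(train_manifest, tmp_path):
    balanced = balance_classes(train_manifest, target_per_class=6, seed=0,
                               out_dir=tmp_path / "aug")
    again = balance_classes(balanced, target_per_class=6, seed=1,
                            out_dir=tmp_path / "aug2")
    pd.testing.assert_frame_equal(balanced, again)


def test_balance_target_below_class_size_rejected(train_manifest):
    with pytest.raises(ValidationError):
        balance_classes(train_manifest, target_per_class=5)


def test_balanced_target_rule():
    assert balanced_target({"roar": 61, "rumble": 76, "trumpet": 50}) == 80


def test_expand_fourfold_is_five_x(train_manifest, tmp_path):
    out = expand_fourfold(train_manifest, seed=0, out_dir=tmp_path / "aug")
    assert len(out) == 5 * len(train_manifest)
    for lab, n in train_manifest["label"].value_counts().items():
        assert (out["label"] == lab).sum() == 5 * n
    kinds = out.loc[out["provenance"] != "original", "provenance"].str.split(":").str[1]
    assert set(kinds) == {"time_stretch", "pitch_shift", "combined", "gaussian_noise"}

    empty = expand_fourfold(train_manifest.iloc[0:0], seed=0)
    assert len(empty) == 0


def test_augmentation_never_touches_test_split(train_manifest):
    split = stratified_split(train_manifest.assign(split=""), seed=0)
    tagged = apply_split(train_manifest, split)
    with pytest.raises(ValidationError, match="test"):
        expand_fourfold(tagged, seed=0)
    with pytest.raises(ValidationError, match="test"):
        balance_classes(tagged, target_per_class=10, seed=0)


def test_seed_changes_waveforms_not_counts(small_call_clips):
    a = expand_clips_fourfold(small_call_clips, seed=0)
    b = expand_clips_fourfold(small_call_clips, seed=1)
    again = expand_clips_fourfold(small_call_clips, seed=0)
    assert len(a) == len(b) == 5 * len(small_call_clips)
    assert any(not np.array_equal(x.samples, y.samples) for x, y in zip(a, b))
    assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, again))
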