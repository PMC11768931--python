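"""Audio I/O, standardization, trimming, and the stratified split rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from callernet.audio import (
    AudioClip, AudioIOError, ValidationError, apply_split, load_audio,
    resample, save_wav, split_counts, standardize_duration, stratified_split,
    trim_silence,
)


def test_wav_round_trip_within_pcm16_quantization(tmp_path):
    rng = np.random.default_rng(0)
    clip = AudioClip(rng.uniform(-0.8, 0.8, 16_000).astype(np.float32), 16_000)
    save_wav(clip, tmp_path / "a.wav")
    loaded = load_audio(tmp_path / "a.wav")
    assert loaded.sample_rate == 16_000
    assert np.abs(loaded.samples - clip.samples).max() <= 2 ** -15


def test_stereo_loads_as_channel_mean(tmp_path):
    left = np.full(1000, 0.5)
    right = np.full(1000, -0.25)
    data = (np.stack([left, right], axis=1) * 32767).astype(np.int16)
    wavfile.write(tmp_path / "st.wav", 8000, data)
    clip = load_audio(tmp_path / "st.wav")
    assert clip.samples.ndim == 1
    assert abs(clip.samples.mean() - 0.125) < 1e-3


def test_missing_file_raises_with_path(tmp_path):
    with pytest.raises(AudioIOError, match="nowhere.wav"):
        load_audio(tmp_path / "nowhere.wav")


def test_resampling_doubles_length():
    clip = AudioClip(np.random.default_rng(1).standard_normal(8000) * 0.1, 8000)
    up = resample(clip, 16_000)
    assert abs(len(up.samples) - 16_000) <= 1


@pytest.mark.parametrize("mode", ["pad", "truncate", "repeat"])
def test_standardize_duration_modes_and_idempotence(mode):
    sr = 16_000
    rng = np.random.default_rng(2)
    clip = AudioClip(rng.uniform(-0.5, 0.5, 3 * sr), sr)
    out = standardize_duration(clip, 6.0, mode=mode)
    assert len(out.samples) == 6 * sr
    if mode == "pad":
        assert np.all(out.samples[3 * sr:] == 0)
    if mode == "repeat":
        assert np.array_equal(out.samples[:sr], out.samples[3 * sr:4 * sr])
    again = standardize_duration(out, 6.0, mode=mode)
    assert np.array_equal(out.samples, again.samples)

    long = AudioClip(rng.uniform(-0.5, 0.5, 8 * sr), sr)
    cut = standardize_duration(long, 6.0, mode=mode)
    assert np.array_equal(cut.samples, long.samples[:6 * sr])


def test_trim_silence_keeps_the_tone():
    sr = 16_000
    t = np.arange(2 * sr) / sr
    tone = 0.5 * np.sin(2 * np.pi * 440 * t)
    clip = AudioClip(np.concatenate([np.zeros(sr), tone, np.zeros(sr)]), sr)
    trimmed = trim_silence(clip, threshold_db=-40.0)
    assert abs(trimmed.duration_s - 2.0) < 0.05  # within one analysis frame

    silent = AudioClip(np.zeros(sr), sr)
    assert np.array_equal(trim_silence(silent).samples, silent.samples)

    loud = AudioClip(0.5 * np.sin(2 * np.pi * 100 * np.arange(sr) / sr), sr)
    assert np.array_equal(trim_silence(loud).samples, loud.samples)


def _manifest(sizes: dict[str, int]) -> pd.DataFrame:
    rows = [{"clip_id": f"{lab}_{i}", "path": "", "label": lab,
             "split": "", "provenance": "original"}
            for lab, n in sizes.items() for i in range(n)]
    return pd.DataFrame(rows)


def test_split_counts_match_published_composition():
    assert split_counts(77, (0.8, 0.1, 0.1)) == (61, 8, 8)
    assert split_counts(95, (0.8, 0.1, 0.1)) == (76, 10, 9)
    assert split_counts(63, (0.8, 0.1, 0.1)) == (50, 7, 6)
    assert split_counts(10, (0.8, 0.1, 0.1)) == (8, 1, 1)


def test_stratified_split_partition_identity():
    manifest = _manifest({"roar": 77, "rumble": 95, "trumpet": 63})
    split = stratified_split(manifest, seed=4)
    tagged = apply_split(manifest, split)
    assert set(tagged["split"]) == {"train", "val", "test"}
    assert len(tagged) == 235 and tagged["split"].notna().all()
    for lab, (ntr, nv, nte) in split.per_class_counts.items():
        sub = tagged[tagged["label"] == lab]["split"].value_counts()
        assert (sub.get("train", 0), sub.get("val", 0), sub.get("test", 0)) == (ntr, nv, nte)
    # same seed reproduces membership; different seed moves clips around
    again = stratified_split(manifest, seed=4)
    assert again.assignment == split.assignment
    other = stratified_split(manifest, seed=5)
    assert other.assignment != split.assignment
    assert other.per_class_counts == split.per_class_counts


def test_unlabelled_clips_rejected_by_split():
    manifest = _manifest({"roar": 3})
    manifest.loc[1, "label"] = ""
    with pytest.raises(ValidationError, match="roar_1"):
        stratified_split(manifest)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(n=st.integers(min_value=3, max_value=500))
def test_split_count_identity_for_any_class_size(n):
    ntr, nv, nte = split_counts(n, (0.8, 0.1, 0.1))
    assert ntr + nv + nte == n
    assert ntr == int(np.floor(0.8 * n))
    assert nv - nte in (0, 1)  # validation takes the larger remainder half
    assert min(ntr, nv, nte) >= 0
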