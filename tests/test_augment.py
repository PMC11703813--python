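"""Noise injection, clipping, expansion multiplicities, and splitting."""

import numpy as np
import pytest

from bruitnet.augment import (
    DegenerateInputError,
    add_white_noise,
    clip_segments,
    expand_and_balance,
    split_dataset,
)
from bruitnet.bruit_synth import BruitParams, generate_bruit

from .conftest import sine_recording


def _bruits(n_normal, n_abnormal, duration=24.0, seed0=500):
    recs = []
    for i in range(n_normal + n_abnormal):
        label = "normal" if i < n_normal else "abnormal"
        rec = generate_bruit(BruitParams(label, duration=duration, seed=seed0 + i))
        recs.append(rec.with_samples(rec.samples, id=f"o{i}-{label}"))
    return recs


class TestAddWhiteNoise:
    def test_snr_calibration(self):
        # unit-RMS sine at 20 dB SNR: residual noise RMS must be 0.1 +- 1%
        rec = sine_recording(amplitude=np.sqrt(2) * 0.5)  # RMS = 0.5
        out = add_white_noise(rec, snr_db=20.0, seed=3)
        residual = out.samples.astype(np.float64) - rec.samples
        expected_rms = 0.5 / 10.0
        assert np.sqrt(np.mean(residual**2)) == pytest.approx(expected_rms, rel=0.01)
        assert out.provenance == "noise_augmented"
        assert out.parent_id == rec.id

    def test_measured_snr_within_tenth_db(self):
        rec = sine_recording(amplitude=0.3)
        out = add_white_noise(rec, snr_db=15.0, seed=9)
        residual = out.samples.astype(np.float64) - rec.samples
        snr = 10 * np.log10(np.mean(rec.samples.astype(np.float64) ** 2) / np.mean(residual**2))
        assert abs(snr - 15.0) < 0.1

    def test_very_high_snr_is_identity_limit(self):
        rec = sine_recording()
        out = add_white_noise(rec, snr_db=100.0, seed=3)
        assert np.abs(out.samples - rec.samples).max() < 1e-4

    def test_seeded_determinism(self):
        rec = sine_recording()
        a = add_white_noise(rec, 20.0, seed=5)
        b = add_white_noise(rec, 20.0, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_silent_input_rejected(self):
        silent = sine_recording(amplitude=0.0)
        with pytest.raises(DegenerateInputError):
            add_white_noise(silent, 20.0, seed=1)


class TestClipSegments:
    def test_durations_and_containment(self, normal_bruit):
        short, long_ = clip_segments(normal_bruit, seed=11)
        assert 3.0 <= short.duration <= 6.0
        assert 18.0 <= long_.duration <= 21.0
        assert short.provenance == "clip_3_6"
        assert long_.provenance == "clip_18_21"
        # contiguous sub-arrays of the source
        src = normal_bruit.samples
        for clip in (short, long_):
            n = len(clip.samples)
            matches = [
                s for s in range(len(src) - n + 1)
                if np.array_equal(src[s : s + n], clip.samples)
            ]
            assert matches, "clip is not a contiguous segment of its source"

    def test_labels_inherited(self, abnormal_bruit):
        short, long_ = clip_segments(abnormal_bruit, seed=2)
        assert short.label == long_.label == "abnormal"

    def test_too_short_rejected(self):
        rec = sine_recording(duration=10.0)
        with pytest.raises(ValueError):
            clip_segments(rec, seed=1)


class TestExpandAndBalance:
    def test_minimal_multiplicities(self):
        out = expand_and_balance(_bruits(1, 1), seed=3)
        assert len(out) == 8  # 2 normal variants + 6 abnormal variants
        assert sum(r.label == "normal" for r in out) == 2
        assert sum(r.label == "abnormal" for r in out) == 6

    def test_balances_3_to_1_imbalance(self):
        out = expand_and_balance(_bruits(6, 2), seed=3)
        assert sum(r.label == "normal" for r in out) == 12
        assert sum(r.label == "abnormal" for r in out) == 12

    def test_ids_unique_and_parented(self):
        out = expand_and_balance(_bruits(2, 2), seed=3)
        ids = [r.id for r in out]
        assert len(set(ids)) == len(ids)
        assert all(r.parent_id is not None for r in out)

    def test_labels_conserved(self):
        originals = _bruits(2, 2)
        by_parent = {r.id: r.label for r in originals}
        for rec in expand_and_balance(originals, seed=3):
            assert rec.label == by_parent[rec.parent_id]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            expand_and_balance(_bruits(2, 0), seed=3)


class TestSplitDataset:
    def test_ten_recordings_split_7_1_2(self):
        # stratified floor-rounding, remainder to train: 10 -> 7/1/2
        recs = [
            sine_recording(label=label).with_samples(
                sine_recording().samples, id=f"r{i}-{label}"
            )
            for i, label in enumerate(["normal"] * 5 + ["abnormal"] * 5)
        ]
        split = split_dataset(recs, seed=4)
        assert split.counts() == {"train": 7, "validation": 1, "test": 2}
        for part in (split.train, split.validation, split.test):
            labels = [r.label for r in part]
            assert abs(labels.count("normal") - labels.count("abnormal")) <= 1

    def test_membership_deterministic(self):
        recs = _bruits(4, 4)
        expanded = expand_and_balance(recs, seed=1)
        s1 = split_dataset(expanded, seed=9)
        s2 = split_dataset(expanded, seed=9)
        assert [r.id for r in s1.train] == [r.id for r in s2.train]
        assert [r.id for r in s1.test] == [r.id for r in s2.test]

    def test_splits_disjoint(self):
        expanded = expand_and_balance(_bruits(4, 4), seed=1)
        split = split_dataset(expanded, seed=9)
        ids = [r.id for part in (split.train, split.validation, split.test) for r in part]
        assert len(ids) == len(set(ids)) == len(expanded)

    def test_group_by_parent_prevents_sibling_leakage(self):
        expanded = expand_and_balance(_bruits(6, 6), seed=1)
        split = split_dataset(expanded, seed=9, group_by_parent=True)
        parent_split = {}
        for part_name in ("train", "validation", "test"):
            for rec in getattr(split, part_name):
                assert parent_split.setdefault(rec.parent_id, part_name) == part_name

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], seed=0)
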