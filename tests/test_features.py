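"""Feature fusion front end: pre-emphasis, mel/MFCC, normalization, shapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.fft import dct

from bruitnet.audio_io import AudioRecording
from bruitnet.features import (
    FusedFeature,
    PreEmphasisParams,
    compute_mel_spectrogram,
    compute_mfcc,
    featurize,
    finalize,
    fuse,
    mel_band_centers,
    normalize_columns,
    pre_emphasize,
)

from .conftest import sine_recording


def _rec(samples, rate=16_000):
    return AudioRecording(np.asarray(samples, np.float32), rate, "normal", "t")


class TestPreEmphasis:
    def test_unit_impulse_response(self):
        out = pre_emphasize(_rec([1.0, 0.0, 0.0]))
        assert out.samples == pytest.approx([1.0, -0.97, 0.0])

    def test_all_zero_input(self):
        out = pre_emphasize(_rec(np.zeros(100)))
        assert np.all(out.samples == 0)

    def test_constant_input(self):
        out = pre_emphasize(_rec(np.full(50, 0.5)))
        assert out.samples[0] == pytest.approx(0.5)
        assert out.samples[1:] == pytest.approx(np.full(49, 0.015), abs=1e-6)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            PreEmphasisParams(mu=1.0)

    def test_highpass_response_rises_with_frequency(self):
        # |H(f)| = |1 - mu e^{-i 2 pi f}|: 0.03 at DC, monotone rising to Nyquist
        impulse = np.zeros(512)
        impulse[0] = 1.0
        h = pre_emphasize(_rec(impulse)).samples
        mag = np.abs(np.fft.rfft(h))
        assert mag[0] == pytest.approx(0.03, abs=1e-6)
        assert np.all(np.diff(mag) > -1e-9)


class TestMelSpectrogram:
    def test_shape_is_128_by_128(self, normal_bruit):
        assert compute_mel_spectrogram(pre_emphasize(normal_bruit)).shape == (128, 128)

    def test_short_clip_same_shape(self):
        assert compute_mel_spectrogram(sine_recording(duration=3.0)).shape == (128, 128)

    def test_silence_is_finite_constant(self):
        mel = compute_mel_spectrogram(_rec(np.zeros(16_000)))
        assert np.all(np.isfinite(mel))
        assert np.ptp(mel) == 0.0

    def test_tone_peaks_at_nearest_band(self):
        mel = compute_mel_spectrogram(sine_recording(freq=1000.0, duration=2.0))
        centers = mel_band_centers()
        expected_band = int(np.argmin(np.abs(centers - 1000.0)))
        peak_band = int(np.argmax(mel.mean(axis=1)))
        assert abs(peak_band - expected_band) <= 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_mel_spectrogram(_rec(np.zeros(100)))


class TestMfcc:
    def test_shape_is_13_by_128(self, normal_bruit):
        assert compute_mfcc(pre_emphasize(normal_bruit)).shape == (13, 128)

    def test_matches_direct_dct_oracle(self, normal_bruit):
        """MFCC columns equal a brute-force DCT-II of the log-mel columns.

        Because the time resize is linear and acts on the other axis, the
        DCT commutes with it, so the oracle can work from the resized
        log-mel matrix directly.
        """
        rec = pre_emphasize(normal_bruit)
        logmel = compute_mel_spectrogram(rec)
        mfcc = compute_mfcc(rec)
        n = logmel.shape[0]
        # direct orthonormal DCT-II summation, no fft library
        k = np.arange(13)[:, None]
        i = np.arange(n)[None, :]
        basis = np.cos(np.pi * k * (2 * i + 1) / (2 * n))
        scale = np.where(k == 0, np.sqrt(1.0 / n), np.sqrt(2.0 / n))
        oracle = (scale * basis) @ logmel
        assert np.abs(oracle - mfcc).max() < 1e-6

    def test_silence_rows_constant(self):
        mfcc = compute_mfcc(_rec(np.zeros(16_000)))
        assert np.allclose(np.ptp(mfcc, axis=1), 0.0)


class TestNormalizeColumns:
    def test_hand_example(self):
        out = normalize_columns(np.array([[2.0], [4.0], [6.0]]))
        assert out[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zeros(self):
        out = normalize_columns(np.full((3, 2), 5.0))
        assert np.all(out == 0.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_range_and_idempotence(self, seed):
        mat = np.random.default_rng(seed).normal(size=(6, 5))
        out = normalize_columns(mat)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert np.allclose(normalize_columns(out), out)

    def test_nonconstant_columns_attain_bounds(self, rng):
        out = normalize_columns(rng.normal(size=(10, 4)))
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)


class TestFuseAndFinalize:
    def test_fusion_block_structure(self, rng):
        mel = normalize_columns(rng.normal(size=(128, 128)))
        mfcc = normalize_columns(rng.normal(size=(13, 128)))
        fused = fuse(mel, mfcc)
        assert fused.shape == (141, 128)
        assert np.array_equal(fused[:128], mel)
        assert np.array_equal(fused[128], mfcc[0])
        assert np.array_equal(fused[128:], mfcc)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse(rng.normal(size=(127, 128)), rng.normal(size=(13, 128)))

    def test_finalize_shape_and_range(self, rng):
        fused = fuse(
            normalize_columns(rng.normal(size=(128, 128))),
            normalize_columns(rng.normal(size=(13, 128))),
        )
        final = finalize(fused)
        assert final.values.shape == (128, 141, 1)
        assert final.values.min() >= 0.0
        assert final.values.max() <= 1.0

    def test_finalize_idempotent_fixed_point(self, rng):
        fused = fuse(
            normalize_columns(rng.normal(size=(128, 128))),
            normalize_columns(rng.normal(size=(13, 128))),
        )
        once = finalize(fused).values[:, :, 0].T
        twice = finalize(once).values[:, :, 0].T
        assert np.allclose(once, twice)


class TestFeaturize:
    @pytest.mark.parametrize("duration", [3.0, 21.0])
    def test_duration_invariant_shape(self, duration):
        feature = featurize(sine_recording(duration=duration))
        assert feature.values.shape == (128, 141, 1)

    def test_deterministic(self, normal_bruit):
        a = featurize(normal_bruit)
        b = featurize(normal_bruit)
        assert np.array_equal(a.values, b.values)

    def test_valid_fused_feature_on_bruit(self, abnormal_bruit):
        feature = featurize(abnormal_bruit)
        assert isinstance(feature, FusedFeature)
        assert feature.label == "abnormal"
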