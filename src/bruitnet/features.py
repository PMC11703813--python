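"""Mel-spectrogram + MFCC feature fusion front end.

Pipeline: pre-emphasis (y[n] = x[n] - mu*x[n-1], mu = 0.97) -> STFT with a
25 ms Hann window and 10 ms hop -> 128-band HTK mel filter bank ->
log power.  The log-mel matrix is time-resized to 128 frames (the Mel
spectrogram); its DCT-II per frame, truncated to 13 coefficients and
likewise resized, gives the MFCC matrix.  Both are min-max normalized per
time frame, stacked along the feature axis into a (141, 128) matrix,
normalized again, and shaped to the (time=128, feature=141, channel=1)
model input.

Time-axis standardization uses linear interpolation so clips from 3 s to
30 s all map to the same (128, 141, 1) tensor.  Because interpolation acts
along time and the DCT along the band axis, the two commute: the MFCC
matrix equals the DCT-II of the resized log-mel matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct

from .audio_io import AudioRecording

N_MELS = 128
N_MFCC = 13
N_FRAMES = 128
WIN_S = 0.025
HOP_S = 0.010
N_FFT = 512
LOG_FLOOR = 1e-10
FMIN = 0.0
FMAX = 8000.0


@dataclass(frozen=True)
class PreEmphasisParams:
    """First-order high-pass coefficient, 0 <= mu < 1 (default 0.97)."""

    mu: float = 0.97

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must satisfy 0 <= mu < 1")


@dataclass
class FusedFeature:
    """The (time=128, feature=141, channel=1) fused model input in [0, 1]."""

    values: np.ndarray
    id: str = ""
    label: str = "normal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FRAMES, N_MELS + N_MFCC, 1):
            raise ValueError(f"expected shape (128, 141, 1), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("feature values outside [0, 1]")


def pre_emphasize(rec: AudioRecording, params: PreEmphasisParams = PreEmphasisParams()) -> AudioRecording:
    """Boost high frequencies: y[0] = x[0]; y[n] = x[n] - mu*x[n-1]."""
    x = rec.samples
    if len(x) == 0:
        raise ValueError("empty recording")
    y = np.empty_like(x, dtype=np.float64)
    y[0] = x[0]
    y[1:] = x[1:] - params.mu * x[:-1].astype(np.float64)
    return rec.with_samples(y)


def hz_to_mel(f):
    """HTK mel scale: 2595 * log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filter_bank(
    n_mels: int = N_MELS, n_fft: int = N_FFT, rate: int = 16_000,
    fmin: float = FMIN, fmax: float = FMAX,
) -> np.ndarray:
    """Triangular mel filters, (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_band_centers(n_mels: int = N_MELS, fmin: float = FMIN, fmax: float = FMAX) -> np.ndarray:
    """Center frequency (Hz) of each mel band."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(mel_pts)[1:-1]


def _log_mel_frames(rec: AudioRecording) -> np.ndarray:
    """Log mel-band power per STFT frame, shape (128, n_frames)."""
    x = rec.samples.astype(np.float64)
    nwin = int(round(WIN_S * rec.rate))
    hop = int(round(HOP_S * rec.rate))
    if len(x) < nwin:
        raise ValueError(f"recording shorter than one {WIN_S*1000:.0f} ms window")
    _, _, z = signal.stft(
        x, fs=rec.rate, window="hann", nperseg=nwin, noverlap=nwin - hop,
        nfft=N_FFT, boundary=None, padded=False,
    )
    power = np.abs(z) ** 2  # (n_fft//2+1, n_frames)
    mel_power = mel_filter_bank(rate=rec.rate) @ power
    return 10.0 * np.log10(np.maximum(mel_power, LOG_FLOOR))


def _resize_time(mat: np.ndarray, n_frames: int = N_FRAMES) -> np.ndarray:
    """Linearly interpolate each row to exactly ``n_frames`` columns."""
    t_src = np.linspace(0.0, 1.0, mat.shape[1])
    t_dst = np.linspace(0.0, 1.0, n_frames)
    return np.stack([np.interp(t_dst, t_src, row) for row in mat])


def compute_mel_spectrogram(rec: AudioRecording) -> np.ndarray:
    """Log-mel spectrogram resized to (128 bands, 128 frames)."""
    return _resize_time(_log_mel_frames(rec))


def compute_mfcc(rec: AudioRecording) -> np.ndarray:
    """First 13 orthonormal DCT-II coefficients per frame, (13, 128)."""
    logmel = _log_mel_frames(rec)
    coeffs = dct(logmel, type=2, axis=0, norm="ortho")[:N_MFCC]
    return _resize_time(coeffs)


def normalize_columns(mat: np.ndarray) -> np.ndarray:
    """Min-max scale each column to [0, 1]; constant columns map to zeros."""
    mat = np.asarray(mat, dtype=np.float64)
    lo = mat.min(axis=0, keepdims=True)
    hi = mat.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (mat - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


def fuse(mel_norm: np.ndarray, mfcc_norm: np.ndarray) -> np.ndarray:
    """Stack normalized mel (128,128) over MFCC (13,128) -> (141, 128)."""
    if mel_norm.shape != (N_MELS, N_FRAMES) or mfcc_norm.shape != (N_MFCC, N_FRAMES):
        raise ValueError(
            f"expected (128,128) and (13,128), got {mel_norm.shape} and {mfcc_norm.shape}"
        )
    return np.vstack([mel_norm, mfcc_norm])


def finalize(fused: np.ndarray, id: str = "", label: str = "normal") -> FusedFeature:
    """Renormalize per frame, transpose to time-major, add channel axis."""
    if fused.shape != (N_MELS + N_MFCC, N_FRAMES):
        raise ValueError(f"expected (141, 128), got {fused.shape}")
    final = normalize_columns(fused)
    return FusedFeature(values=final.T[:, :, np.newaxis], id=id, label=label)


def featurize(
    rec: AudioRecording, params: PreEmphasisParams = PreEmphasisParams()
) -> FusedFeature:
    """Full front end: pre-emphasis -> mel + MFCC -> normalize -> fuse."""
    emphasized = pre_emphasize(rec, params)
    logmel = _log_mel_frames(emphasized)  # one STFT feeds both branches
    mel = normalize_columns(_resize_time(logmel))
    coeffs = dct(logmel, type=2, axis=0, norm="ortho")[:N_MFCC]
    mfcc = normalize_columns(_resize_time(coeffs))
    return finalize(fuse(mel, mfcc), id=rec.id, label=rec.label)


def featurize_many(recordings) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Featurize an iterable of recordings.

    Returns (features (N,128,141,1) float32, labels (N,) 0=normal/1=abnormal,
    ids).
    """
    feats, labels, ids = [], [], []
    for rec in recordings:
        f = featurize(rec)
        feats.append(f.values.astype(np.float32))
        labels.append(1 if rec.label == "abnormal" else 0)
        ids.append(rec.id)
    if not feats:
        return np.zeros((0, N_FRAMES, N_MELS + N_MFCC, 1), np.float32), np.zeros(0, int), []
    return np.stack(feats), np.asarray(labels, dtype=np.int64), ids
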