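"""WAV ingestion and export with the pipeline's rate/channel conventions.

All downstream stages assume 16 kHz mono audio with amplitudes in [-1, 1].
Labels and provenance travel in manifests (CSV) or JSON sidecars, never in
the WAV itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_RATE = 16_000

#: provenance values for original and augmented recordings
PROVENANCES = (
    "original",
    "noise_augmented",
    "clip_3_6",
    "clip_18_21",
    "clip_3_6_noise",
    "clip_18_21_noise",
)

LABELS = ("normal", "abnormal")


class AudioFormatError(ValueError):
    """Unreadable, corrupt, or empty WAV input."""


@dataclass
class AudioRecording:
    """A labelled mono waveform.

    Parameters
    ----------
    samples:
        Amplitudes in [-1, 1], float32.
    rate:
        Sampling rate in Hz (16 kHz after ingestion).
    label:
        ``"normal"`` or ``"abnormal"``.
    id:
        Unique identifier within a dataset.
    provenance:
        How the recording came to be (original vs augmented variant).
    parent_id:
        Id of the source recording for augmented variants.
    """

    samples: np.ndarray
    rate: int
    label: str
    id: str
    provenance: str = "original"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def validate(self) -> None:
        """Raise if invariants are violated (finiteness, amplitude bound)."""
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")
        if len(self.samples) and float(np.abs(self.samples).max()) > 1.0 + 2**-15:
            raise ValueError("amplitude exceeds [-1, 1]")

    def with_samples(self, samples: np.ndarray, **changes) -> "AudioRecording":
        return replace(self, samples=np.asarray(samples, dtype=np.float32), **changes)


def _to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass floats through."""
    if data.dtype == np.int16:
        return data.astype(np.float32) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float32) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float32) - 128.0) / 128.0
    if data.dtype in (np.float32, np.float64):
        return data.astype(np.float32)
    raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")


def load_wav(
    path: str | Path,
    target_rate: int = TARGET_RATE,
    label: str = "normal",
    id: str | None = None,
) -> AudioRecording:
    """Read a WAV file as a mono recording at ``target_rate``.

    Multi-channel audio is averaged to mono; other sampling rates are
    polyphase-resampled.  Amplitudes are scaled to [-1, 1] (peak-safe: if the
    source exceeds full scale it is renormalized).  A JSON sidecar written by
    :func:`save_wav` (``<path>.json``) overrides ``label``/``id`` metadata.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - scipy raises assorted types
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"empty audio in {path}")
    x = _to_float(data)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(target_rate, int(rate))
        x = resample_poly(x.astype(np.float64), frac.numerator, frac.denominator)
        x = x.astype(np.float32)
    peak = float(np.abs(x).max())
    if peak > 1.0:
        x = x / peak
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return AudioRecording(
        samples=x,
        rate=target_rate,
        label=meta.get("label", label),
        id=meta.get("id", id if id is not None else path.stem),
        provenance=meta.get("provenance", "original"),
        parent_id=meta.get("parent_id"),
    )


def save_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV plus a JSON metadata sidecar.

    Round-tripping through :func:`load_wav` reproduces samples within the
    16-bit quantization step (max abs error <= 2**-15) at equal rates.
    """
    rec.validate()
    path = Path(path)
    q = np.clip(np.round(rec.samples.astype(np.float64) * 32767.0), -32768, 32767)
    wavfile.write(path, rec.rate, q.astype(np.int16))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "id": rec.id,
                "label": rec.label,
                "provenance": rec.provenance,
                "parent_id": rec.parent_id,
                "rate": rec.rate,
            }
        )
    )


def check_original_duration(rec: AudioRecording) -> bool:
    """Whether a recording satisfies the 24-30 s convention for originals."""
    return 24.0 - 1e-9 <= rec.duration <= 30.0 + 1e-9


def derive_seed(base_seed: int, *indices: int) -> int:
    """A stable child seed below 2**31 derived from a base seed and indices."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _require_positive(value: float, name: str) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number")
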