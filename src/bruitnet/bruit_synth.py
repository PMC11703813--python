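"""Seeded synthetic AVF bruit generator.

Clinical shunt-sound corpora are not public, so this module emulates the
qualitative class contrast reported for real fistula sounds: a healthy
(normal) bruit carries relatively uniform broadband energy across the
spectrum, while a stenotic (abnormal) bruit is weaker overall with its energy
scattered into intermittent narrowband components.

Signal model
------------
A periodic train of Gaussian-windowed systolic pulses (cardiac modulation at
``heart_rate``) amplitude-modulates pink-ish broadband turbulence noise
shaped by a low-pass envelope.  For the abnormal class the broadband
envelope is attenuated by ``1 - 0.5 * separation`` and randomized short tone
bursts (scattered narrowband energy) are superimposed, their amplitude
growing with ``separation``.  At ``separation = 0`` the two classes are
drawn from the same distribution; class separability is monotone in
``separation``.

No hemodynamic model of the diameter-to-sound mapping is attempted: the
stenosis criterion (fistula diameter < 1.8 mm) enters only as the binary
label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .audio_io import AudioRecording, derive_seed

#: peak broadband amplitude; leaves headroom so |sample| <= 1 without
#: per-recording renormalization (which would erase the class power contrast)
_BASE_AMPLITUDE = 0.18

_NOISE_LOWPASS_HZ = 3000.0  # turbulence band of a bruit
_PULSE_WIDTH_S = 0.06  # systolic pulse half-width
_BURST_RATE_PER_S = 1.0  # abnormal narrowband bursts per second
_BURST_WIDTH_S = 0.05


@dataclass(frozen=True)
class BruitParams:
    """Generation parameters for one synthetic shunt sound.

    duration is in seconds within [24, 30] (the nominal recording length);
    separation in [0, 1] controls the normal/abnormal spectral contrast
    (0 = indistinguishable classes); heart_rate is in beats per second.
    """

    label: str = "normal"
    duration: float = 27.0
    rate: int = 16_000
    heart_rate: float = 1.2
    separation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("normal", "abnormal"):
            raise ValueError(f"label must be normal/abnormal, got {self.label!r}")
        if not 24.0 <= self.duration <= 30.0:
            raise ValueError("duration must be within [24, 30] s")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be within [0, 1]")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


def _pulse_envelope(n: int, rate: int, heart_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Cardiac amplitude modulation: Gaussian pulses at the beat period."""
    period = rate / heart_rate
    # impulse train with slight beat-to-beat jitter, convolved with a Gaussian
    impulses = np.zeros(n)
    t = rng.uniform(0, 0.2) * period
    while t < n:
        impulses[int(t)] = 1.0
        t += period * (1.0 + 0.03 * rng.standard_normal())
    width = int(_PULSE_WIDTH_S * rate)
    kernel = signal.windows.gaussian(6 * width + 1, std=width)
    env = signal.fftconvolve(impulses, kernel, mode="same")
    # diastolic floor: the bruit never fully silences between beats
    return 0.35 + 0.65 * env / max(env.max(), 1e-12)


def _turbulence(n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    """Pink-ish broadband noise band-limited to the bruit's turbulence range."""
    white = rng.standard_normal(n)
    # one-pole low-shelf gives the ~1/f tilt of flow noise
    tilted = signal.lfilter([1.0], [1.0, -0.6], white)
    sos = signal.butter(4, _NOISE_LOWPASS_HZ, fs=rate, output="sos")
    shaped = signal.sosfilt(sos, tilted)
    return shaped / max(float(shaped.std()), 1e-12)


def _narrow_bursts(
    n: int, rate: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Intermittent tone bursts carrying the 'scattered' abnormal energy."""
    out = np.zeros(n)
    n_bursts = rng.poisson(_BURST_RATE_PER_S * n / rate)
    width = int(_BURST_WIDTH_S * rate)
    tt = np.arange(-3 * width, 3 * width + 1)
    window = np.exp(-0.5 * (tt / width) ** 2)
    for _ in range(n_bursts):
        center = rng.integers(3 * width, max(n - 3 * width, 3 * width + 1))
        freq = rng.uniform(300.0, 3000.0)
        phase = rng.uniform(0, 2 * np.pi)
        tone = np.sin(2 * np.pi * freq * tt / rate + phase) * window
        lo = center - 3 * width
        out[lo : lo + tone.size] += tone[: n - lo]
    return out * 0.35 * separation


def generate_bruit(params: BruitParams) -> AudioRecording:
    """Synthesize one labelled shunt sound, deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.rate))
    env = _pulse_envelope(n, params.rate, params.heart_rate, rng)
    noise = _turbulence(n, params.rate, rng)
    x = _BASE_AMPLITUDE * env * noise
    if params.label == "abnormal":
        x = x * (1.0 - 0.5 * params.separation)
        x = x + _BASE_AMPLITUDE * env * _narrow_bursts(n, params.rate, params.separation, rng)
    x = np.clip(x, -1.0, 1.0)
    return AudioRecording(
        samples=x.astype(np.float32),
        rate=params.rate,
        label=params.label,
        id=f"{params.label}-{params.seed:010d}",
        provenance="original",
    )


def iter_dataset(
    n_normal: int,
    n_abnormal: int,
    params: BruitParams = BruitParams(),
    seed: int = 0,
) -> Iterator[AudioRecording]:
    """Lazily generate a labelled dataset (normals first).

    Durations are sampled uniformly in [24, 30] s; each recording gets a seed
    derived from ``seed`` and its index, so any prefix is reproducible.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be >= 0")
    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    for i, label in enumerate(labels):
        item_seed = derive_seed(seed, i)
        duration = float(np.random.default_rng(derive_seed(seed, i, 1)).uniform(24.0, 30.0))
        p = replace(params, label=label, duration=duration, seed=item_seed)
        rec = generate_bruit(p)
        yield replace(rec, id=f"orig-{i:04d}-{label}")


def manifest_from(recordings: list[AudioRecording]) -> pd.DataFrame:
    """Tabulate recordings as a dataset manifest."""
    return pd.DataFrame(
        {
            "id": [r.id for r in recordings],
            "label": [r.label for r in recordings],
            "provenance": [r.provenance for r in recordings],
            "parent_id": [r.parent_id for r in recordings],
            "duration": [round(r.duration, 6) for r in recordings],
        }
    )


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    params: BruitParams = BruitParams(),
    seed: int = 0,
) -> tuple[list[AudioRecording], pd.DataFrame]:
    """Generate ``n_normal + n_abnormal`` recordings plus their manifest."""
    recs = list(iter_dataset(n_normal, n_abnormal, params, seed))
    return recs, manifest_from(recs)


def band_power(rec: AudioRecording, f_lo: float = 0.0, f_hi: float = 2000.0) -> float:
    """Mean spectral power in [f_lo, f_hi] Hz (Welch estimate).

    The simple band-power statistic used to verify class separability.
    """
    f, pxx = signal.welch(rec.samples, fs=rec.rate, nperseg=2048)
    mask = (f >= f_lo) & (f <= f_hi)
    return float(pxx[mask].mean())
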