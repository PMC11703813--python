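import numpy as np
import pytest

from bruitnet.audio_io import AudioRecording
from bruitnet.bruit_synth import BruitParams, generate_bruit


@pytest.fixture(scope="session")
def normal_bruit() -> AudioRecording:
    return generate_bruit(BruitParams(label="normal", duration=24.0, seed=101))


@pytest.fixture(scope="session")
def abnormal_bruit() -> AudioRecording:
    return generate_bruit(BruitParams(label="abnormal", duration=24.0, seed=202))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def sine_recording(freq=440.0, duration=1.0, rate=16_000, amplitude=0.5, label="normal"):
    t = np.arange(int(duration * rate)) / rate
    return AudioRecording(
        samples=(amplitude * np.sin(2 * np.pi * freq * t)).astype(np.float32),
        rate=rate,
        label=label,
        id=f"sine-{freq:g}",
    )
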