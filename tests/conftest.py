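import json

import numpy as np
import pytest

from avdeid import synthetic
from avdeid.audioscrub import AudioBuffer


@pytest.fixture
def greeting_doc() -> str:
    """Two-segment diarized document with a plantable name at 67358-68798 ms."""
    return json.dumps(
        {
            "language": "en",
            "duration_ms": 70000,
            "segments": [
                {
                    "start": 50.122, "end": 51.163,
                    "text": "So we're back again.", "speaker": "SPEAKER_00",
                    "words": [
                        {"word": "So", "start": 50.122, "end": 50.31, "score": 0.98},
                        {"word": "we're", "start": 50.35, "end": 50.62, "score": 0.97},
                        {"word": "back", "start": 50.66, "end": 50.9, "score": 0.99},
                        {"word": "again.", "start": 50.94, "end": 51.163, "score": 0.95},
                    ],
                },
                {
                    "start": 67.358, "end": 68.798,
                    "text": "Margaret, it's nice to meet you.",
                    "speaker": "SPEAKER_01",
                    "words": [
                        {"word": "Margaret,", "start": 67.358, "end": 68.798,
                         "score": 0.92},
                    ],
                },
            ],
        }
    )


@pytest.fixture
def short_spec() -> synthetic.FixtureSpec:
    return synthetic.FixtureSpec(seed=11, duration_s=10.0)


def make_harmonic(f0: float, seconds: float = 2.0, sr: int = 16000) -> AudioBuffer:
    """Synthetic vowel: 5 harmonics with geometrically decaying amplitudes."""
    t = np.arange(int(seconds * sr)) / sr
    x = sum(0.25 * 0.7 ** (k - 1) * np.sin(2 * np.pi * k * f0 * t)
            for k in range(1, 6))
    return AudioBuffer(x, sr)
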