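import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oxipulse import SynthConfig, generate_recording
from oxipulse.preprocessing import preprocess_recording
from oxipulse.segmentation import segment_recording


@pytest.fixture(scope="session")
def small_recording():
    """Half-hour recording with default effect sizes, shared across tests."""
    return generate_recording(SynthConfig(duration_h=0.5, event_rate_per_h=20, seed=1))


@pytest.fixture(scope="session")
def small_preprocessed(small_recording):
    return preprocess_recording(small_recording)


@pytest.fixture(scope="session")
def small_segments(small_recording):
    return segment_recording(small_recording)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free recording for beat-recovery oracles."""
    return generate_recording(
        SynthConfig(duration_h=0.5, event_rate_per_h=10, noise_sd=0.0, seed=4)
    )


def match_beats(planted_times, planted_values, detected_times, tol=0.25):
    """Pair detected beats with the nearest planted beat within ``tol`` s."""
    idx = np.clip(np.searchsorted(planted_times, detected_times), 1, len(planted_times) - 1)
    nearest = np.where(
        np.abs(planted_times[idx] - detected_times)
        < np.abs(planted_times[idx - 1] - detected_times),
        idx,
        idx - 1,
    )
    ok = np.abs(planted_times[nearest] - detected_times) < tol
    return planted_values[nearest[ok]], ok
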