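"""Shared fixtures: small synthetic sessions reused across test modules."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from gaitstab.synth import ArtifactSpec, SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    """A light session: 16 channels, 500 Hz, 60 s."""
    return SessionConfig(n_subjects=2, trial_duration=60.0,
                         sampling_rate_eeg=500.0, n_channels=16, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, "NW", 0)


@pytest.fixture(scope="session")
def artifact_session():
    """64-channel session with blinks and EMG bursts injected."""
    cfg = SessionConfig(
        trial_duration=60.0, sampling_rate_eeg=250.0, n_channels=64, seed=5,
        artifact_spec=ArtifactSpec(blink_rate=0.2, emg_rate=0.05))
    return generate_session(cfg, "NW", 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
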