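import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from diversitrace.synthgen import GeneratorConfig, build_design, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A light 3-condition session: 2 presentations x 30 s, 3 channels, 250 Hz."""
    design = build_design(
        conditions=["100", "backward", "resting-state"],
        presentations_per_condition=2,
        presentation_duration_s=30.0,
        sampling_rate_hz=250.0,
        n_channels=3,
        seed=42,
    )
    cfg = GeneratorConfig(seed=7)
    return generate_session(design, cfg)


def noise_epoch(rng, n_channels=1, n_samples=2500):
    """White-noise epoch: the maximally diverse reference signal."""
    return rng.standard_normal((n_channels, n_samples))
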