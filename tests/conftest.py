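"""Shared fixtures: small synthetic datasets and frame batches."""

import numpy as np
import pytest

from imuhar.synthetic_data import SyntheticConfig, make_frames_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 short, balanced, low-noise recordings — enough structure for every
    pipeline stage without long runtimes."""
    cfg = SyntheticConfig.easy_benchmark(seed=7)
    cfg.n_recordings = 4
    cfg.duration_s = 90.0
    return make_frames_dataset(cfg)


@pytest.fixture(scope="session")
def frame_batch(rng):
    """A random (10, 24, 120) frame batch."""
    return rng.normal(size=(10, 24, 120))


@pytest.fixture(scope="session")
def single_frame(rng):
    return rng.normal(size=(24, 120))
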