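import numpy as np
import pytest

from seizuregraph import (
    ModelConfig,
    SyntheticSpec,
    evenly_spaced_seizures,
    generate_recording,
    prepare_recording,
    rebalance_pool,
)


@pytest.fixture(scope="session")
def small_recording():
    """120-s two-seizure recording with clearly separable ictal windows."""
    spec = SyntheticSpec(
        duration_s=120.0,
        seizure_intervals=[(20.0, 35.0), (70.0, 90.0)],
        seed=1,
    )
    return generate_recording(spec)


@pytest.fixture(scope="session")
def small_segments(small_recording):
    segs = prepare_recording(small_recording)
    return rebalance_pool(segs, 5.0, seed=0)


@pytest.fixture
def tiny_config():
    """A small architecture for fast unit tests (6 channels, 64 samples)."""
    return ModelConfig(
        n_channels=6,
        window_samples=64,
        gcn_dim=8,
        classifier_channels=(4, 8),
        seed=0,
    )


@pytest.fixture
def tiny_layout():
    from seizuregraph import ElectrodeLayout

    pts = np.random.default_rng(7).uniform(-1, 1, (6, 2))
    return ElectrodeLayout([f"ch{i}" for i in range(6)], pts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
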