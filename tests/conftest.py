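import numpy as np
import pytest

import restsync as rs


@pytest.fixture(scope="session")
def montage():
    return rs.default_montage()


@pytest.fixture(scope="session")
def adjacency(montage):
    return rs.build_adjacency(montage)


@pytest.fixture(scope="session")
def tiny_study():
    """A small simulated two-group study shared by expensive tests."""
    cfg = rs.default_study_config(duration_s=10.0, n_per_group=(3, 3), seed=11)
    recordings, truth = rs.simulate_group_study(cfg)
    return cfg, recordings, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data: np.ndarray, fs: float = 256.0, labels=None) -> rs.EpochedRecording:
    """Continuous recording from a (n_channels, n_samples) array."""
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return rs.EpochedRecording(data=data[:, None, :], fs=fs, labels=labels)
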