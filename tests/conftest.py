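import numpy as np
import pytest

from intseg import SimulationConfig, make_partition, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_partition():
    """Minimal legal partition: 7 networks x 2 ROIs."""
    return make_partition(14, [2] * 7)


@pytest.fixture
def small_partition():
    """7 networks x 4 ROIs; large enough for non-degenerate efficiency nulls."""
    return make_partition(28, [4] * 7)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact 9-state cohort reused by pipeline-level tests."""
    cfg = SimulationConfig(
        seed=424242,
        n_rois=28,
        network_sizes=(4,) * 7,
        n_frames=40,
        n_subjects_per_state=5,
    )
    return simulate_cohort(cfg)


def random_symmetric_weights(rng, n, low=-0.3, high=0.95):
    """Random symmetric weight matrix with unit diagonal (some negatives)."""
    w = rng.uniform(low, high, (n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w
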