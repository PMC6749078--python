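import numpy as np
import pytest

from metastate import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A quick-to-generate planted dataset: 4 subjects x 2 sessions,
    3 states over 24 regions, 60 windows."""
    return SyntheticSpec(
        n_subjects=4,
        n_states=3,
        n_regions=24,
        windows_per_session=60,
        window_width_volumes=12,
        mean_dwell=8.0,
        snr=5.0,
        retest_rho=0.8,
        seed=42,
    )


def random_symmetric(rng, n, density=1.0, low=0.0, high=1.0):
    """A random symmetric weighted matrix with zero diagonal."""
    A = rng.uniform(low, high, size=(n, n))
    if density < 1.0:
        A[rng.random((n, n)) > density] = 0.0
    A = np.triu(A, k=1)
    return A + A.T
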