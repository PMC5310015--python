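import numpy as np
import pytest

from tskcca.kernels import ViewMatrix, feature_wise_bank, normalize_bank


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_bank(rng, n=10, d=3, normalized=True):
    """Small random feature-wise bank for oracle comparisons."""
    view = ViewMatrix(rng.normal(size=(n, d)))
    bank = feature_wise_bank(view)
    return normalize_bank(bank) if normalized else bank


@pytest.fixture
def bank_pair(rng):
    return random_bank(rng, n=10, d=3), random_bank(rng, n=10, d=2)
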