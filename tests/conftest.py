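import numpy as np
import pytest
from scipy.stats import binom


def binom99_bounds(n: int, p: float) -> tuple[float, float]:
    """Exact binomial central 99% acceptance region for a rejection rate."""
    return binom.ppf(0.005, n, p) / n, binom.ppf(0.995, n, p) / n


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gxe_data(rng):
    """A modest dataset with genuine main and interaction effects."""
    n, k = 120, 4
    X = rng.integers(0, 3, (n, k)).astype(float)
    z = rng.standard_normal(n)
    y = 0.4 * X[:, 0] + 0.3 * z + 0.5 * X[:, 1] * z + rng.standard_normal(n)
    return y, X, z
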