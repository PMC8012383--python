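import numpy as np
import pytest

from howlid import F0Contour


@pytest.fixture
def four_point_contour():
    """The hand-checked 4-sample grid contour used across feature tests."""
    return F0Contour(
        "toy4",
        times=np.array([0.0, 0.1, 0.2, 0.3]),
        freqs=np.array([400.0, 430.0, 460.0, 400.0]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160203)


def random_irregular_contour(rng, n_min=5, n_max=60):
    """A random digitised-style contour with irregular time spacing."""
    n = int(rng.integers(n_min, n_max))
    times = np.cumsum(rng.uniform(0.01, 0.2, size=n))
    freqs = rng.uniform(150.0, 900.0, size=n)
    return F0Contour(f"rand{rng.integers(1 << 30)}", times=times, freqs=freqs)
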