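import numpy as np
import pytest

from lungdens import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Standard phantom: 10% subpleural emphysema, 3 HU noise."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same geometry with zero noise, for exact-value checks."""
    return generate_phantom(PhantomSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A compact grid for brute-force oracle comparisons."""
    def make(seed, **kw):
        defaults = dict(grid_shape=(40, 48, 48), seed=seed)
        defaults.update(kw)
        return PhantomSpec(**defaults)

    return make
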