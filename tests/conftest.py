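import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_design(rng):
    """Random traits + covariates + genotype for regression oracles."""
    n, r, l = 50, 3, 2
    H = rng.standard_normal((n, l))
    x = rng.binomial(2, 0.3, n).astype(float)
    Y = rng.standard_normal((n, r)) + 0.3 * x[:, None] + H @ rng.standard_normal((l, r))
    return Y, H, x
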