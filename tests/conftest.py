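import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def bvn_sample(rng, n, rho, mu=(0.0, 0.0), sigma=(1.0, 1.0)):
    """Correlated bivariate normal draws for estimator tests."""
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    return mu[0] + sigma[0] * x, mu[1] + sigma[1] * y
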