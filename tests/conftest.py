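import numpy as np
import pandas as pd
import pytest

from gradientzi.synthgen import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study, shared read-only across tests."""
    return simulate_study(SyntheticConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def zip_dataset():
    """Moderate zero-inflated Poisson dataset with known truth."""
    rng = np.random.default_rng(123)
    n = 2000
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    lam = np.exp(1.0 + 0.5 * x)
    pi = 1.0 / (1.0 + np.exp(1.0 + 0.8 * z))
    y = rng.poisson(lam)
    y[rng.random(n) < pi] = 0
    return pd.DataFrame({"y": y, "x": x, "z": z}), \
        {"beta": (1.0, 0.5), "gamma": (-1.0, -0.8)}
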