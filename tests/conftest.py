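import numpy as np
import pandas as pd
import pytest

from nanoqrastr import workflow


@pytest.fixture(scope="session")
def external():
    """The 35-compound external prediction table fixture."""
    return workflow.external_table()


@pytest.fixture(scope="session")
def oxide_formulas(external):
    return external["formula"].tolist()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def linear_dataset():
    """Small synthetic regression set with a strong known linear signal."""
    ds = workflow.synth_dataset(n=30, p=4, noise_sd=0.5, seed=7)
    return ds


def random_regression(seed, n=25, p=3, noise=1.0):
    """Plain random linear dataset used by property-style loops."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{j}" for j in range(p)]
    )
    beta = rng.uniform(-2, 2, p)
    y = X.to_numpy() @ beta + rng.normal(0, noise, n)
    return X, y
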