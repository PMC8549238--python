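import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_intake():
    """Five subjects, four food-group columns in g/d."""
    return pd.DataFrame(
        {
            "Butter": [10.0, 5.0, 8.0, 12.0, 3.0],
            "Margarine": [2.0, 4.0, 1.0, 3.0, 5.0],
            "Fresh fruit": [150.0, 80.0, 200.0, 120.0, 90.0],
            "Tea": [300.0, 250.0, 400.0, 350.0, 200.0],
        },
        index=pd.Index(["a", "b", "c", "d", "e"], name="subject_id"),
    )


@pytest.fixture
def standardized_gaussian(rng):
    """200 x 6 correlated normal table indexed by subject."""
    from dietnet import preprocess

    cov = np.eye(6)
    cov[0, 1] = cov[1, 0] = 0.6
    cov[2, 3] = cov[3, 2] = 0.4
    x = rng.multivariate_normal(np.zeros(6), cov, size=200, method="cholesky")
    table = pd.DataFrame(
        x,
        columns=[f"g{i}" for i in range(6)],
        index=pd.Index([f"S{i}" for i in range(200)], name="subject_id"),
    )
    return preprocess.standardize(table)
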