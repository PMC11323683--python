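import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def small_problem(rng):
    """A clean n=30, p=3 regression with known coefficients."""
    from spatialipod import RegressionProblem

    X = rng.normal(size=(30, 3))
    beta = np.array([1.0, -2.0, 0.5])
    y = X @ beta + 0.05 * rng.normal(size=30)
    return RegressionProblem(X, y), beta
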