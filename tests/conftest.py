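import numpy as np
import pytest

from ssenet import DesignData, SimScenario, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_logistic_data(n=40, j=5, seed=7, intercept=0.3):
    """Small non-separable logistic dataset for solver tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, j))
    beta = np.zeros(j)
    beta[: min(2, j)] = [1.0, -0.5][: min(2, j)]
    p = 1.0 / (1.0 + np.exp(-(intercept + X @ beta)))
    y = rng.binomial(1, p)
    if len(np.unique(y)) < 2:  # pragma: no cover - seed chosen to avoid this
        raise RuntimeError("degenerate fixture")
    return DesignData.from_arrays(X, y)


@pytest.fixture
def small_data():
    return make_logistic_data()


#: 10x10 lattice analogue of the full study condition, scaled for fast tests:
#: 13-location disc, correlated predictors, ~30% event rate at N = 80.
TINY_SCENARIO = SimScenario(
    n_rows=10,
    n_cols=10,
    n_subjects=80,
    signal_value=0.5,
    signal_radius=2.0,
    predictor_mean=-0.5,
    seed=0,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(TINY_SCENARIO)
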