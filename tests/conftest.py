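import numpy as np
import pytest

from profilemix import IndicatorMatrix, ParameterSet, default_scenario, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raw_data():
    """4 subjects × 2 indicators, raw scale."""
    values = np.array([
        [10.0, 1.0],
        [20.0, 2.0],
        [40.0, 3.0],
        [50.0, 4.0],
    ])
    return IndicatorMatrix(values, ["s1", "s2", "s3", "s4"], ["vrt", "fsiq"])


@pytest.fixture
def random_data(rng):
    """20 subjects × 3 indicators of plain Gaussian noise."""
    return IndicatorMatrix(
        rng.standard_normal((20, 3)),
        [f"s{i}" for i in range(20)],
        ["a", "b", "c"],
    )


@pytest.fixture
def random_params(rng):
    return ParameterSet(
        proportions=np.array([0.3, 0.7]),
        means=rng.standard_normal((2, 3)),
        variances=np.array([0.5, 1.0, 2.0]),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study from the default 5-class scenario (n=120)."""
    return simulate(default_scenario(seed=7))


@pytest.fixture(scope="session")
def two_class_sim():
    """Well-separated two-class, one-indicator Gaussian mixture, n=200."""
    rng = np.random.default_rng(99)
    z = rng.random(200) < 0.5
    y = np.where(z, 2.0, -2.0) + rng.standard_normal(200)
    return IndicatorMatrix(y[:, None], [f"s{i}" for i in range(200)], ["y"]), z
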