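import numpy as np
import pytest

from phaspasto import TimeSeries, simulate_lorenz_x


@pytest.fixture(scope="session")
def lorenz_x1():
    """Benchmark Lorenz x-series for one interpolation point per gap."""
    return simulate_lorenz_x(1)


@pytest.fixture(scope="session")
def lorenz_x5():
    return simulate_lorenz_x(5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240718)


@pytest.fixture
def short_series():
    """Small non-trivial observed series with non-equidistant times."""
    return TimeSeries([0.0, 1.0, 2.5, 3.0, 4.0], [3.0, 7.0, 5.0, 6.5, 4.0])
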