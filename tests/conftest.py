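import numpy as np
import pytest

import migtrend as mt


@pytest.fixture(scope="session")
def small_season():
    """Short season for fast fitting tests."""
    return mt.SeasonConfig(ndays=30, peak_day=15.0, spread=5.0)


@pytest.fixture(scope="session")
def null_dataset():
    """One 20-year dataset with constant phi = 0.5 and no trend."""
    scen = mt.ScenarioSpec(trend_pct=0.0, phi=mt.make_phi_schedule("constant", 0.5, 0.5, 20))
    return mt.simulate_dataset(scen, seed=20240, n1=3000, sigma_annual=0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
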