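import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_campaign():
    """A short (n=300) default campaign shared across tests."""
    from sourcerisk.synthetic_data import simulate_default_campaign

    table, truth, spec = simulate_default_campaign(seed=11, n_samples=300)
    return table, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_table():
    """A 4-sample, 3-species table in internal units."""
    from sourcerisk.speciation_io import SpeciesTable

    idx = pd.date_range("2018-11-01", periods=4, freq="h")
    df = pd.DataFrame({"OC": [1000.0, 1200.0, 900.0, 1100.0],
                       "Cr": [5.0, 6.0, 7.0, 8.0],
                       "As": [8.0, 9.0, 10.0, 11.0]}, index=idx)
    return SpeciesTable(df)
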