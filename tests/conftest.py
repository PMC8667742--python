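import numpy as np
import pandas as pd
import pytest

from fallowcast.synthetic import GeneratorConfig, gen_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default 10-year, 69-plot generated dataset (the trial-shaped layout)."""
    return gen_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def long_dataset():
    """150-year, 3-plot dataset used for signal-recovery checks (450 rows).

    Many distinct years at a small per-year replicate count keeps the
    year-level signal learnable instead of memorizable.
    """
    return gen_dataset(GeneratorConfig(seed=0, years=150, plots_per_year=3))


@pytest.fixture()
def simple_weather():
    """Two flat calendar years of hand-written monthly weather."""
    rows = []
    for year in (2000, 2001):
        for month in range(1, 13):
            rows.append(
                {
                    "year": year,
                    "month": month,
                    "precip": 40.0,
                    "t_mean": 14.0,
                    "t_max": 20.0,
                    "t_min": 8.0,
                    "sunshine": 200.0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
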