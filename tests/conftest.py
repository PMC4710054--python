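import numpy as np
import pandas as pd
import pytest

from alcopol.population import SHARE_COLUMNS, classify_individuals
from alcopol.synthetic_data import (PopulationConfig, PriceConfig,
                                    generate_population,
                                    generate_transactions)


@pytest.fixture(scope="session")
def population():
    """A seeded mid-size synthetic population, classified."""
    return classify_individuals(
        generate_population(PopulationConfig(n=4000, seed=7)))


@pytest.fixture(scope="session")
def transactions(population):
    return generate_transactions(population, PriceConfig(seed=8))


@pytest.fixture()
def tiny_individuals():
    """Three hand-built drinkers spanning the drinking levels."""
    rows = []
    for pid, sex, band, mean, peak in [
        ("a", "male", "25-34", 10.0, 3.0),     # moderate (80 g/wk)
        ("b", "male", "35-44", 30.0, 8.0),     # hazardous (240 g/wk)
        ("c", "female", "45-54", 40.0, 12.0),  # harmful (320 g/wk)
    ]:
        row = {"person_id": pid, "sex": sex, "age_band": band,
               "weight": 1.0, "mean_weekly_units": mean,
               "peak_day_units": peak}
        for col in SHARE_COLUMNS:
            row[col] = 1.0 / len(SHARE_COLUMNS)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
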