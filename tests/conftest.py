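import warnings

import numpy as np
import pandas as pd
import pytest

from devgraph import (
    CountryTable,
    IndicatorSpec,
    default_config,
    generate_table,
    score_table,
)


@pytest.fixture(scope="session")
def default_table():
    """Study-shaped synthetic table: 194 countries, 54 indicators."""
    return generate_table(default_config(seed=7))


@pytest.fixture(scope="session")
def scored_default(default_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return score_table(default_table)


@pytest.fixture
def small_registry():
    return [
        IndicatorSpec("literacy", "Adult literacy", "socioeconomic",
                      "higher_desirable", False, "%"),
        IndicatorSpec("stunting", "Stunting under 5", "infancy_under5",
                      "lower_desirable", False, "%"),
        IndicatorSpec("water", "Basic water services", "wash",
                      "higher_desirable", False, "%"),
    ]


@pytest.fixture
def small_table(small_registry):
    data = pd.DataFrame(
        {
            "literacy": [60.0, 75.0, np.nan, 90.0, 99.0],
            "stunting": [40.0, 25.0, 30.0, 10.0, 5.0],
            "water": [50.0, 65.0, 70.0, 85.0, 95.0],
        },
        index=pd.Index(["AAA", "BBB", "CCC", "DDD", "EEE"], name="country"),
    )
    income = pd.Series(
        ["low", "low", "lower_middle", "upper_middle", "high"], index=data.index
    )
    return CountryTable(data=data, income_class=income, registry=small_registry)
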