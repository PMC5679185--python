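import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gfrens.equations import AgeRangeWarning

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _silence_age_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AgeRangeWarning)
        yield


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    """Six patients spanning all four equation branches, with measured GFR."""
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(6)],
            "age": [40.0, 62.0, 55.0, 70.0, 35.0, 48.0],
            "sex": ["female", "female", "male", "male", "female", "male"],
            "scr": [0.8, 2.4, 0.9, 3.1, 1.2, 1.0],
            "mgfr": [95.0, 28.0, 88.0, 21.0, 72.0, 80.0],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
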