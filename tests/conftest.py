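import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_series():
    """Tiny 1-s count series: worn, all wake."""
    from actibout.preprocess import CountsSeries

    return CountsSeries(
        start_time=pd.Timestamp("2024-01-01 00:00:00"),
        epoch=1,
        counts=np.array([0.0, 5.0, 5.0, 1.0, 0.0, 7.0, 0.0]),
    )
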