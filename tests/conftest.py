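import numpy as np
import pandas as pd
import pytest

from somprofiler.cohort import ProfileSpec, VariableDef
from somprofiler.tracegen import Bout, CountTraceSpec, DaySpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_var_specs():
    """Two tiny, well-separated 2-variable profiles for fast tests."""
    variables = (
        VariableDef("a", 0.0, 10.0),
        VariableDef("b", 0.0, 10.0),
    )
    return [
        ProfileSpec(
            name="low",
            size=15,
            girl_fraction=0.5,
            locations={"a": 2.0, "b": 2.0},
            spreads={"a": 0.5, "b": 0.5},
            variables=variables,
        ),
        ProfileSpec(
            name="high",
            size=15,
            girl_fraction=0.5,
            locations={"a": 8.0, "b": 8.0},
            spreads={"a": 0.5, "b": 0.5},
            variables=variables,
        ),
    ]


def standard_day(day_type="weekday", mvpa_minutes=30):
    """A 600-minute day: sedentary + one MVPA bout + light activity."""
    return DaySpec(
        day_type,
        (
            Bout("sedentary", 300, 50.0),
            Bout("mvpa", mvpa_minutes, 3000.0),
            Bout("light", 600 - 300 - mvpa_minutes, 1000.0),
        ),
    )


@pytest.fixture
def valid_trace_spec():
    """3 weekdays + 1 weekend day, 30 MVPA min each, all days valid."""
    return CountTraceSpec(
        participant_id="P1",
        days=[standard_day("weekday")] * 3 + [standard_day("weekend")],
        seed=7,
    )
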