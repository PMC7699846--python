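from datetime import datetime, timedelta

import numpy as np
import pytest

import crowdwatch as cw
from crowdwatch.records import CST


@pytest.fixture(scope="session")
def small_scenario():
    """A compact 12-hour scenario with a 2-hour event, for fast tests."""
    return cw.ScenarioConfig(
        start=datetime(2014, 12, 31, 12, 0, tzinfo=CST),
        end=datetime(2015, 1, 1, 0, 0, tzinfo=CST),
        background_rate=60.0,
        event_window=(
            datetime(2014, 12, 31, 20, 0, tzinfo=CST),
            datetime(2014, 12, 31, 22, 0, tzinfo=CST),
        ),
        event_hourly_multipliers=(1.0, 2.0),
        event_rate_scale=60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_scenario):
    return cw.generate_scenario(small_scenario)


@pytest.fixture
def grid_5x5():
    grid = cw.GridSpec(0.0, 0.0, 2.0, 5, 5)
    return grid, cw.queen_weights(grid)


def make_record(i=0, hour=12, minute=0, lon=121.49, lat=31.24, tokens=("a",)):
    return cw.CheckInRecord(
        id=f"t{i}",
        timestamp=datetime(2014, 12, 31, hour, minute, tzinfo=CST),
        lon=lon,
        lat=lat,
        tokens=tuple(tokens),
    )
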