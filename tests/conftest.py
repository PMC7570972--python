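import datetime as dt

import numpy as np
import pytest

import residentirl as ri


@pytest.fixture(scope="session")
def open_plan():
    """A 6x9 obstacle-free grid with the two sensors of the worked example."""
    return ri.Floorplan(
        n_rows=6,
        n_cols=9,
        sensor_cell={"M007": (3, 2), "M004": (2, 4)},
        location_of={(3, 2): "livingroom", (2, 4): "kitchen"},
    )


@pytest.fixture(scope="session")
def sim_floorplan():
    return ri.make_floorplan(seed=1)


@pytest.fixture(scope="session")
def sim_home(sim_floorplan):
    """A 12-day simulated home (recovery profile), shared across tests."""
    return ri.simulate_home("h1", sim_floorplan, ri.recovery_profile(), 12, seed=3)


@pytest.fixture(scope="session")
def prepared_home(sim_home, sim_floorplan):
    return ri.prepare_home(sim_home.events, sim_floorplan)


def make_day_events(date, cells_and_times, floorplan):
    """Events at given (seconds, sensor_id) pairs on one calendar day."""
    day_start = dt.datetime.combine(date, dt.time.min)
    return [
        ri.SensorEvent(day_start + dt.timedelta(seconds=s), sid, "ON")
        for s, sid in cells_and_times
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
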