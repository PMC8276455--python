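import numpy as np
import pandas as pd
import pytest

from windrift import synthetic_data as sd
from windrift.geodesy import GeoPoint


@pytest.fixture(scope="session")
def autumn_scenario() -> sd.WindScenario:
    """Study-conditions wind scenario: 8 m/s easterlies/monsoon flow around a
    seasonally shifting ITF line over an African-flyway domain."""
    return sd.WindScenario()


@pytest.fixture(scope="session")
def autumn_grid(autumn_scenario):
    return sd.make_wind_grid(autumn_scenario)


@pytest.fixture(scope="session")
def calm_grid():
    """Zero-wind grid (spring window) for geometry-only checks."""
    return sd.make_wind_grid(sd.WindScenario(U0=0.0, v_amp=0.0, t0="2020-04-05"))


@pytest.fixture
def toy_fixes() -> pd.DataFrame:
    """A two-day track: one travel day due north at ~56 km/h, one stop day."""
    rows = []
    t0 = pd.Timestamp("2019-10-20 06:00:00")
    lat = 20.0
    for h in range(10):
        rows.append({"bird_id": "B1", "t": t0 + pd.Timedelta(hours=h), "lon": 0.0, "lat": lat})
        lat += 0.5
    t1 = pd.Timestamp("2019-10-21 06:00:00")
    for h in range(10):
        rows.append({"bird_id": "B1", "t": t1 + pd.Timedelta(hours=h), "lon": 0.0, "lat": lat})
    return pd.DataFrame(rows)


def simulate(policy_kwargs, grid, start=GeoPoint(-13.5, 29.4), t0="2019-10-16", seed=1):
    pol = sd.BehaviourPolicy(**policy_kwargs)
    return sd.simulate_track(pol, grid, start, t0, seed=seed)
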