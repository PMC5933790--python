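"""Shared fixtures: small simulated deployments reused across test modules."""

import warnings

import pandas as pd
import pytest
from hypothesis import settings

from adlsense.pipeline import run_micro_scenario
from adlsense.simulate import (AIAEpisode, AnomalySchedule, default_profile,
                               simulate_home)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def small_deployment(profile):
    """10 days with one of each anomaly type, plus a dropout window."""
    schedule = AnomalySchedule(
        visitor_days=frozenset({3}),
        away_days=frozenset({5}),
        dropout=(("motion_kitchen", (7, 8)),),
        aia_episodes=(AIAEpisode(9, 14, 18, physio_vitals=("heart_rate",)),),
    )
    events, truth = simulate_home(profile, schedule, days=10, seed=42)
    return events, truth, schedule


@pytest.fixture(scope="session")
def micro_result():
    """One full micro-track run shared by scoring/HMM/fusion-level checks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_micro_scenario(1)


def make_events(rows, home_id="h1"):
    """Build a minimal event frame from (timestamp, sensor_id, type, value)."""
    return pd.DataFrame(
        [(pd.Timestamp(ts), home_id, sid, stype, "loc", val)
         for ts, sid, stype, val in rows],
        columns=["timestamp", "home_id", "sensor_id", "sensor_type",
                 "location", "value"],
    )
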