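import numpy as np
import pandas as pd
import pytest

import baybudgets as bb
from baybudgets.synthetic import fixture_hand_tally, small_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    """The committed toy dataset: (sightings, acoustic, scans)."""
    return small_fixture()


@pytest.fixture(scope="session")
def hand_tally():
    """Hand-counted expectations committed alongside the toy dataset."""
    return fixture_hand_tally()


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


def make_scans(states, location="Makako", platform="BOAT", follow_id="F1",
               counts=None, start="2011-01-01T08:00", step_min=10):
    """Build a minimal valid scan table from a list of activity states."""
    n = len(states)
    times = pd.date_range(start, periods=n, freq=f"{step_min}min")
    if counts is None:
        counts = [(0, 0, 0)] * n
    boats, kayaks, swimmers = zip(*counts)
    return pd.DataFrame(
        {
            "follow_id": follow_id,
            "timestamp": times,
            "platform": platform,
            "location": location,
            "activity": list(states),
            "n_boats": boats,
            "n_kayaks": kayaks,
            "n_swimmers": swimmers,
        }
    )


@pytest.fixture
def scans_builder():
    return make_scans
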