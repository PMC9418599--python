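import numpy as np
import pandas as pd
import pytest

from tapjid.jid_core import JIDConfig
from tapjid.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return JIDConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-participant synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n_participants=25, seed=7, days=8))


@pytest.fixture
def simple_events():
    return pd.DataFrame(
        {
            "participant_id": ["a", "a", "a", "b", "b"],
            "timestamp_ms": [0, 100, 350, 10_000, 10_050],
            "app_id": ["x", "x", "y", "x", "x"],
        }
    )


@pytest.fixture
def simple_episodes():
    return pd.DataFrame(
        {
            "participant_id": ["a", "b"],
            "on_ms": [-10, 9_000],
            "off_ms": [500, 11_000],
        }
    )
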