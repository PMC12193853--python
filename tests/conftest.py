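import numpy as np
import pandas as pd
import pytest

from hypowatch import simulate as sim
from hypowatch import timeline as tl
from hypowatch.config import CohortConfig, ModelingConfig, RunConfig


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Two participants, five days: enough structure for schema/smoke checks."""
    return CohortConfig(n_participants=2, days_per_participant=5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def participant(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def assembled(participant):
    return tl.assemble_timeline(participant.streams.values(), participant.participant_id)


@pytest.fixture(scope="session")
def fast_run_config() -> RunConfig:
    """Pipeline config small enough for repeated end-to-end runs in tests."""
    return RunConfig(
        simulate=CohortConfig(
            n_participants=2, days_per_participant=5, day_event_rate=1.2, night_event_rate=0.8
        ),
        modeling=ModelingConfig(n_undersample_seeds=2),
        seed=11,
    )


def minute_index(n: int, start: str = "2024-03-01 08:00") -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq="min")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
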