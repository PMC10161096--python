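import numpy as np
import pandas as pd
import pytest

from setshift.agent import AgentParams, simulate_session
from setshift.task import TaskConfig, build_session_schedule


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def vehicle_log(task_config) -> pd.DataFrame:
    """Trial log of five default-agent vehicle sessions (deterministic)."""
    logs = []
    for i in range(5):
        schedule = build_session_schedule(
            task_config, seed=100 + i, subject_id="subject_1",
            dose_condition="vehicle", session=i,
        )
        logs.append(simulate_session(schedule, seed=200 + i))
    return pd.concat(logs, ignore_index=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
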