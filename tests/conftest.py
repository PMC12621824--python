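import numpy as np
import pandas as pd
import pytest

from patchtime import behavior_analysis as ba
from patchtime import synthetic_data as sd
from patchtime import task_model as tm


@pytest.fixture(scope="session")
def task_config() -> tm.TaskConfig:
    return tm.TaskConfig()


@pytest.fixture(scope="session")
def short_config() -> tm.TaskConfig:
    """Two-block six-minute sessions: fast but with both contexts."""
    return tm.TaskConfig().recalibrated(session_duration=360.0, n_blocks=2)


@pytest.fixture(scope="session")
def policy() -> sd.ExitPolicy:
    return sd.ExitPolicy()


@pytest.fixture(scope="session")
def events(short_config, policy) -> sd.SessionEvents:
    return sd.simulate_session(short_config, policy, seed=101, start_context="low")


@pytest.fixture(scope="session")
def trial_table(events) -> pd.DataFrame:
    return ba.build_trial_table(events)


def make_step_epochs(n, seed, wait_lo=2.0, wait_hi=4.0, gap=0.5):
    """Back-to-back waiting epochs with known intended waits."""
    rng = np.random.default_rng(seed)
    waits = rng.uniform(wait_lo, wait_hi, n)
    starts = np.concatenate([[0.0], np.cumsum(waits + gap)[:-1]])
    return pd.DataFrame(
        dict(visit=np.arange(n), epoch=np.ones(n, dtype=int), start=starts,
             end=starts + waits, kind="reward_exit", intended_wait=waits,
             context="high")
    )


def stub_events_for(epochs: pd.DataFrame, gap: float = 0.5) -> sd.SessionEvents:
    duration = float(epochs["end"].iloc[-1] + gap)
    cfg = tm.TaskConfig().recalibrated(
        session_duration=duration, n_blocks=1, block_duration=duration
    )
    records = pd.DataFrame(
        {"time": [0.0], "event": ["patch_entry"], "context": ["high"]}
    )
    return sd.SessionEvents(records, session_id="stub", config=cfg, epochs=epochs)
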