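import numpy as np
import pandas as pd
import pytest

from flydom import (
    SimConfig,
    derived_seed,
    simulate_contest,
    simulate_truth,
)
from flydom.ethogram_io import EventTable


@pytest.fixture(scope="session")
def established_config():
    """Default conditions restricted to contests that establish."""
    return SimConfig(p_pre_established=0.0, p_never_established=0.0, seed=101)


@pytest.fixture(scope="session")
def sim_contest(established_config):
    """One full-length established contest with trajectory."""
    return simulate_contest(established_config, derived_seed(101, 0), "fixture")


@pytest.fixture(scope="session")
def truth_cohort(established_config):
    """Events-only cohort of 20 established contests (fast)."""
    truths = [
        simulate_truth(established_config, derived_seed(202, i), f"c{i:02d}")
        for i in range(20)
    ]
    events = EventTable(
        pd.concat([t.events.df for t in truths], ignore_index=True)
    )
    timelines = [t.to_timeline(f"c{i:02d}") for i, t in enumerate(truths)]
    return truths, events, timelines


@pytest.fixture(scope="session")
def first_contest():
    """An established first contest plus its config (for rematch designs)."""
    cfg = SimConfig(p_pre_established=0.0, p_never_established=0.0, seed=21)
    return cfg, simulate_contest(cfg, derived_seed(21, 0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
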