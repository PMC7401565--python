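import numpy as np
import pytest

from calfplay.ethogram import BehaviourEvent, EventLog
from calfplay.simulate import SimulationConfig, simulate_cohort


def make_random_log(
    rng: np.random.Generator,
    horizon_s: int = 3600,
    n_events: int = 50,
    calf_id: str = "c0",
) -> EventLog:
    """Random integer-time event log: non-overlapping events with random
    categories, separated by random gaps (so bout merging is non-trivial)."""
    events = []
    t = 0
    codes = {"resting": "l", "active": "t", "play": "p", "meta": "O"}
    for _ in range(n_events):
        gap = int(rng.integers(0, 6))
        dur = int(rng.integers(1, 30))
        start = t + gap
        end = start + dur
        if end > horizon_s:
            break
        cat = rng.choice(["resting", "active", "play"], p=[0.4, 0.35, 0.25])
        events.append(BehaviourEvent(calf_id, codes[cat], cat, start, end))
        t = end
    return EventLog(calf_id, 0, horizon_s, events)


@pytest.fixture(scope="session")
def default_cohort():
    """Ten simulated calves at the default study conditions (48 h)."""
    return simulate_cohort(SimulationConfig(n_calves=10, seed=1))


@pytest.fixture(scope="session")
def holdout_cohort():
    """A second, independent group of ten calves under the same conditions."""
    return simulate_cohort(
        SimulationConfig(n_calves=10, seed=1), calf_indices=list(range(100, 110))
    )
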