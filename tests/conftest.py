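import numpy as np
import pytest

from dendrosim import GrowthSchedule, simulate_ensemble


@pytest.fixture(scope="session")
def tm20_schedule():
    return GrowthSchedule.one_stage(0.360, 0.594, n0=30)


@pytest.fixture(scope="session")
def tm20_ensemble(tm20_schedule):
    """100 wild-type Tm20 neurons, fixed master seed, events recorded."""
    return simulate_ensemble(tm20_schedule, 100, master_seed=1, record_events=True)


@pytest.fixture(scope="session")
def sparse_ensemble():
    """Low-rate regime (k_b=0.02, k_t=0.021): long sparse segments."""
    sched = GrowthSchedule.one_stage(0.02, 0.021, n0=30)
    return simulate_ensemble(sched, 100, master_seed=2)
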