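import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from caniact import SimulationConfig, simulate_activity, simulate_cohort
from caniact.simulate import make_analysis_table


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noise-bearing cohort reused by several suites."""
    cfg = SimulationConfig(
        n_dogs=120,
        records_per_dog_mean=30,
        records_per_dog_dispersion=None,
        anomaly_prob=0.0,
        unlinkable_prob=0.0,
        seed=20,
    )
    dogs, truth = simulate_cohort(cfg)
    activity = simulate_activity(dogs, truth, cfg)
    table = make_analysis_table(dogs, activity)
    return cfg, dogs, truth, table
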