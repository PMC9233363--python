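import numpy as np
import pytest

from mitomethyl.core import build_matrix
from mitomethyl.simulate import AREAS, SimulationConfig, simulate_dataset

# Scaled-down but fully featured study: both areas, planted effects strong
# enough that every index comes out non-empty at n=20+10.
SMALL_SIM = dict(
    genome_length=3000,
    n_control=20,
    n_drug=10,
    n_ba_sites=20,
    n_age_sites=15,
    n_du_sites=10,
    ba_effect=2.0,
    du_effect=3.0,
    age_slope=0.04,
    coverage_mean_H=150,
    coverage_mean_L=60,
)


@pytest.fixture(scope="session")
def small_dataset():
    config = SimulationConfig(**SMALL_SIM, seed=3)
    reference, cohort, truth, calls = simulate_dataset(config)
    return config, reference, cohort, truth, calls


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    _, _, cohort, _, calls = small_dataset
    matrices = {}
    for area in AREAS:
        call_sets = {pid: df for (pid, a), df in calls.items() if a == area}
        matrices[area] = build_matrix(call_sets, min_coverage=30, area=area)
    return cohort, matrices


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
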