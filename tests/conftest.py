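import warnings

import numpy as np
import pytest

from comutpath import SimulationConfig, simulate_cohort
from comutpath.mutation_pathway import build_binary_matrix, compute_tmb, map_to_pathways

# lifelines emits approximation warnings on tiny fits; they are not failures
warnings.filterwarnings("ignore", module="lifelines")


@pytest.fixture(scope="session")
def sim_cohort():
    """One medium synthetic cohort with a planted pair, reused read-only."""
    cfg = SimulationConfig(seed=7, n_samples=600, carrier_fraction=0.2, hazard_ratio=0.6)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_profile(sim_cohort):
    """(matrix, profile, tmb) derived from the shared cohort."""
    matrix = build_binary_matrix(sim_cohort.records, sim_cohort.clinical.ids, 0.01)
    profile = map_to_pathways(matrix, sim_cohort.gene_sets, 0.01)
    tmb = compute_tmb(sim_cohort.records, sim_cohort.clinical.ids)
    return matrix, profile, tmb


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
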