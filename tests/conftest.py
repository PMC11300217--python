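import numpy as np
import pytest
from hypothesis import settings

import sparsemet as sm

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """60-genotype, 6-environment trial used by several suites."""
    return sm.SimulationConfig(
        n_genotypes=60,
        n_markers=400,
        n_families=12,
        reps_per_env=[2] * 6,
        blocks_per_rep=10,
        plots_per_block=9,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_markers(small_config):
    return sm.simulate_marker_matrix(small_config)


@pytest.fixture(scope="session")
def small_kinship(small_markers):
    return sm.vanraden_grm(small_markers)


@pytest.fixture(scope="session")
def small_truth(small_markers, small_config):
    return sm.simulate_true_signals(small_markers, small_config)


@pytest.fixture(scope="session")
def small_grid(small_truth, small_config):
    return sm.simulate_adjusted_phenotypes(small_truth, small_config)
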