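import numpy as np
import pytest

from driversig.synthetic_fixtures import CohortSpec, simulate_cohort

# scaled-down cohort for unit tests; the acceptance suite uses the defaults
SMALL_SPEC = CohortSpec(
    n_genes=120,
    n_cells=30,
    n_drugs=10,
    n_pathways=6,
    pathway_size=(15, 25),
    n_decoy_pathways=6,
    n_driver_genes=12,
    n_driver_modules=3,
    n_fingerprint_bits=32,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
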