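import numpy as np
import pytest

from driverfis import (
    RunConfig,
    SimulationConfig,
    simulate_cohort,
    worked_micro_example,
)


@pytest.fixture(scope="session")
def micro():
    return worked_micro_example()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene, 80-sample cohort with 5 spiked drivers."""
    return simulate_cohort(
        SimulationConfig(n_genes=300, n_samples=80, n_drivers=5, seed=7)
    )


@pytest.fixture(scope="session")
def small_cohort_paths(small_cohort, tmp_path_factory):
    return small_cohort.write(tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def small_run_config(small_cohort_paths):
    return RunConfig(
        maf=small_cohort_paths["maf"],
        fis_table=small_cohort_paths["fis_table"],
        features=small_cohort_paths["features"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
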