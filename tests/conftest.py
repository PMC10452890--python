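import pytest

from riskcluster.fixtures_io import (
    load_fixture,
    load_packaged_knowledgebase,
    load_pedigree_fixture,
)
from riskcluster.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def study_pedigree():
    return load_pedigree_fixture()


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5")


@pytest.fixture(scope="session")
def kb():
    return load_packaged_knowledgebase()


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """One medium synthetic cohort shared across the suite."""
    config = SimulationConfig(seed=20230812, n_small_variants=600, n_svs=300)
    return simulate_cohort(config, tmp_path_factory.mktemp("cohort"))
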