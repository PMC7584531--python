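import pytest
from hypothesis import HealthCheck, settings

from mitovar.cohort import annotate_cohort
from mitovar.haplotree import assign_cohort, default_ignore_list, default_tree
from mitovar.reference import default_gene_model
from mitovar.synthetic import SimulationConfig, paper_fixture, simulate_cohort

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def model():
    return default_gene_model()


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture(scope="session")
def ignore_positions():
    return default_ignore_list()


@pytest.fixture(scope="session")
def fixture_tables():
    return paper_fixture()


@pytest.fixture(scope="session")
def sim_result(model, tree):
    """Paper-scale simulated cohort (47/42), fully annotated and
    haplogroup-called."""
    res = simulate_cohort(SimulationConfig(seed=11), model, tree)
    annotate_cohort(res.cohort, model, res.frequency_table)
    assign_cohort(res.cohort, tree)
    return res


@pytest.fixture(scope="session")
def cohort(sim_result):
    return sim_result.cohort


@pytest.fixture(scope="session")
def big_sim(model, tree):
    """Large cohort (500/500) for parameter-recovery checks."""
    res = simulate_cohort(
        SimulationConfig(seed=2026, n_patients=500, n_controls=500),
        model, tree,
    )
    annotate_cohort(res.cohort, model, res.frequency_table)
    return res
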