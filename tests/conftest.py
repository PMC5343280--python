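import pytest

from glucotrace.network import build_network
from glucotrace.mrm import load_unlabeled_table, turn_shifts
from glucotrace.pathway import propagate
from glucotrace.simulate import CohortConfig, generate_cohort

U13C = (1, 1, 1, 1, 1, 1)


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def u13c_result(network):
    return propagate(network, U13C, 2)


@pytest.fixture(scope="session")
def table1():
    return load_unlabeled_table()


@pytest.fixture(scope="session")
def shifts(u13c_result):
    return turn_shifts(u13c_result)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=7))
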