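import pytest

from herbsub.datasets import load_case_study
from herbsub.relations import RelationTables


@pytest.fixture(scope="session")
def case_study():
    return load_case_study()


@pytest.fixture()
def small_relations():
    """Three drugs sharing one side effect (counts 2, 4, 6) and two sharing
    one indication (counts 1, 3)."""
    return RelationTables(
        drug_se={"A": {"se": 2}, "B": {"se": 4}, "C": {"se": 6}},
        drug_ind={"A": {"ind": 1}, "B": {"ind": 3}},
    )
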