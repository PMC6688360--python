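import numpy as np
import pytest

from mlmda import FixtureConfig, generate_fixture
from mlmda.containers import AssociationMatrix, DiseaseDAG, SequenceRecord


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-block fixture shared by the slower integration tests."""
    return generate_fixture(
        FixtureConfig(n_diseases=24, n_mirnas=32, n_blocks=2, seed=11)
    )


@pytest.fixture
def chain_dag():
    """root -> d: the minimal two-term DAG."""
    return DiseaseDAG("d", frozenset({"d", "root"}), frozenset({("root", "d")}))


@pytest.fixture
def diamond_dag():
    """root -> {a, b} -> d."""
    return DiseaseDAG(
        "d",
        frozenset({"d", "a", "b", "root"}),
        frozenset({("root", "a"), ("root", "b"), ("a", "d"), ("b", "d")}),
    )


@pytest.fixture
def identity_assoc():
    return AssociationMatrix(np.eye(2, dtype=int), ["d1", "d2"], ["m1", "m2"])


def make_records(seqs: dict[str, str]) -> list[SequenceRecord]:
    return [SequenceRecord(k, v) for k, v in seqs.items()]
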