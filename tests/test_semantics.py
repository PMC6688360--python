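import math

import numpy as np
import pytest

from mlmda.containers import DiseaseDAG
from mlmda.semantics import (
    SemanticContribution,
    SemanticParams,
    contributions_model1,
    contributions_model2,
    semantic_matrix,
    semantic_similarity,
)


def chain(disease, *ancestors):
    """Build a linear DAG ancestors[-1] -> ... -> ancestors[0] -> disease."""
    terms = [disease, *ancestors]
    edges = frozenset((terms[i + 1], terms[i]) for i in range(len(terms) - 1))
    return DiseaseDAG(disease, frozenset(terms), edges)


class TestModel1:
    def test_chain_decay(self, chain_dag):
        c = contributions_model1(chain_dag, SemanticParams(delta=0.5))
        assert c.values == {"d": 1.0, "root": 0.5}
        assert c.dv == 1.5

    def test_singleton_dv_is_one(self):
        dag = DiseaseDAG("d", frozenset({"d"}), frozenset())
        assert contributions_model1(dag).dv == 1.0

    def test_diamond_max_over_children(self, diamond_dag):
        c = contributions_model1(diamond_dag, SemanticParams(delta=0.5))
        assert c.values["a"] == c.values["b"] == 0.5
        assert c.values["root"] == 0.25
        assert c.dv == 2.25

    def test_disease_contribution_is_one_and_range(self):
        c = contributions_model1(chain("d", "a", "b", "c"), SemanticParams(0.7))
        assert c.values["d"] == 1.0
        assert all(0 < v <= 1 for v in c.values.values())


class TestModel2:
    def test_term_in_one_of_two_dags(self):
        forest = {"d1": chain("d1", "t"), "d2": chain("d2", "u")}
        contribs = contributions_model2(forest)
        assert contribs["d1"].values["t"] == pytest.approx(math.log(1.5))

    def test_term_in_every_dag_scores_log2(self):
        forest = {f"d{i}": chain(f"d{i}", "shared") for i in range(5)}
        contribs = contributions_model2(forest)
        for c in contribs.values():
            assert c.values["shared"] == pytest.approx(math.log(2))

    def test_log_base_configurable(self):
        forest = {"d1": chain("d1", "t"), "d2": chain("d2", "u")}
        contribs = contributions_model2(forest, SemanticParams(log_base=2))
        assert contribs["d1"].values["t"] == pytest.approx(math.log2(1.5))

    def test_empty_forest_errors(self):
        with pytest.raises(ValueError, match="empty"):
            contributions_model2({})


class TestSimilarity:
    def test_identical_dags_give_one(self):
        c = contributions_model1(chain("d", "a", "root"))
        assert semantic_similarity(c, c) == pytest.approx(1.0)

    def test_disjoint_ancestors_give_zero(self):
        c1 = contributions_model1(chain("d1", "r1"))
        c2 = contributions_model1(chain("d2", "r2"))
        assert semantic_similarity(c1, c2) == 0.0

    def test_two_leaves_under_shared_root(self):
        c1 = contributions_model1(chain("d1", "root"), SemanticParams(0.5))
        c2 = contributions_model1(chain("d2", "root"), SemanticParams(0.5))
        assert semantic_similarity(c1, c2) == pytest.approx((0.5 + 0.5) / 3.0)

    def test_degenerate_dv_errors(self):
        z = SemanticContribution("d", {}, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            semantic_similarity(z, z)

    def test_shared_ancestor_never_decreases_numerator(self):
        """Extending both chains with a shared top term adds contribution mass."""
        params = SemanticParams(0.5)
        for depth in range(1, 5):
            anc = [f"a{i}" for i in range(depth)]
            c1 = contributions_model1(chain("d1", *anc), params)
            c2 = contributions_model1(chain("d2", *anc), params)
            shared = set(c1.values) & set(c2.values)
            num = sum(c1.values[t] + c2.values[t] for t in shared)
            c1x = contributions_model1(chain("d1", *anc, "top"), params)
            c2x = contributions_model1(chain("d2", *anc, "top"), params)
            shared_x = set(c1x.values) & set(c2x.values)
            num_x = sum(c1x.values[t] + c2x.values[t] for t in shared_x)
            assert num_x >= num


def random_forest_of_dags(rng, n_diseases, n_terms):
    """Random chains through a shared term pool (possibly overlapping)."""
    pool = [f"t{i}" for i in range(n_terms)]
    forest = {}
    for i in range(n_diseases):
        depth = int(rng.integers(0, min(4, n_terms) + 1))
        anc = list(rng.choice(pool, size=depth, replace=False))
        forest[f"d{i}"] = chain(f"d{i}", *anc)
    return forest


@pytest.mark.parametrize("model", [1, 2])
def test_matrix_equals_per_pair_oracle(model):
    """Matrix construction agrees with independent per-pair recomputation."""
    rng = np.random.default_rng(13)
    for _ in range(5):
        forest = random_forest_of_dags(rng, int(rng.integers(2, 9)), 10)
        params = SemanticParams(0.5)
        mat = semantic_matrix(forest, params, model=model)
        if model == 1:
            contribs = {d: contributions_model1(g, params) for d, g in forest.items()}
        else:
            contribs = contributions_model2(forest, params)
        for i, a in enumerate(mat.labels):
            for j, b in enumerate(mat.labels):
                expected = semantic_similarity(contribs[a], contribs[b])
                assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_array_equal(mat.values, mat.values.T)
        if model == 1:
            assert np.allclose(np.diag(mat.values), 1.0)
            assert ((mat.values >= 0) & (mat.values <= 1)).all()
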