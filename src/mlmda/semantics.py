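"""Disease semantic similarity from ontology DAGs.

Two complementary models are implemented.  Model 1 scores each ancestor
term of a disease by how far it sits above the disease: the disease itself
contributes 1 and every step up the DAG multiplies the contribution by a
decay factor delta (taking the max over a term's children inside the DAG).
Model 2 scores a term by its specificity across the whole disease set:
log(1 + n_DAGs_containing_term / n_diseases), so terms shared by few
diseases carry more information.  Under either model the semantic value
DV of a disease is the sum of its term contributions, and the similarity
of two diseases is the contribution mass on their shared terms normalised
by DV_i + DV_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .containers import DiseaseDAG, SimilarityMatrix

__all__ = [
    "SemanticParams",
    "SemanticContribution",
    "contributions_model1",
    "contributions_model2",
    "semantic_similarity",
    "semantic_matrix",
]


@dataclass(frozen=True)
class SemanticParams:
    """Decay factor for model 1 and logarithm base for model 2.

    ``delta`` discounts an ancestor's contribution per level of separation
    from the disease; 0.5 is the conventional choice in the hierarchy-based
    disease-similarity literature.  ``log_base`` defaults to the natural
    logarithm.
    """

    delta: float = 0.5
    log_base: float = math.e

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")

    def log(self, x: float) -> float:
        return math.log(x) / math.log(self.log_base)


@dataclass(frozen=True)
class SemanticContribution:
    """Per-term contributions of one disease plus their sum DV."""

    disease_id: str
    values: dict[str, float]
    dv: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dv is None:
            object.__setattr__(self, "dv", float(sum(self.values.values())))


def contributions_model1(
    dag: DiseaseDAG, params: SemanticParams = SemanticParams()
) -> SemanticContribution:
    """Decay-based contributions: 1 at the disease, delta per level above.

    For a term t above the disease, the contribution is
    delta * max over t's children inside the DAG, so the effective weight
    is delta ** (shortest downward distance to the disease).
    """
    memo: dict[str, float] = {}

    def value(term: str) -> float:
        if term == dag.disease_id:
            return 1.0
        if term not in memo:
            children = dag.children_of(term)
            if not children:
                raise ValueError(
                    f"term {term!r} in DAG of {dag.disease_id!r} has no path "
                    "down to the disease"
                )
            memo[term] = params.delta * max(value(c) for c in children)
        return memo[term]

    values = {t: value(t) for t in sorted(dag.ancestors)}
    return SemanticContribution(dag.disease_id, values)


def contributions_model2(
    dag_forest: Mapping[str, DiseaseDAG],
    params: SemanticParams = SemanticParams(),
) -> dict[str, SemanticContribution]:
    """Frequency-based contributions shared across the whole forest.

    A term's score log(1 + df(t) / n) depends only on its document
    frequency df(t) (number of disease DAGs containing it) and the number
    of diseases n; each disease then collects the scores of its own terms.
    """
    if not dag_forest:
        raise ValueError("empty DAG forest")
    n = len(dag_forest)
    df: dict[str, int] = {}
    for dag in dag_forest.values():
        for t in dag.ancestors:
            df[t] = df.get(t, 0) + 1
    term_score = {t: params.log(1.0 + df[t] / n) for t in df}
    return {
        d: SemanticContribution(d, {t: term_score[t] for t in sorted(dag.ancestors)})
        for d, dag in dag_forest.items()
    }


def semantic_similarity(
    c_i: SemanticContribution, c_j: SemanticContribution
) -> float:
    """Shared-term contribution mass normalised by the two semantic values."""
    denom = c_i.dv + c_j.dv
    if denom == 0:
        raise ValueError(
            f"degenerate DAGs: DV({c_i.disease_id}) + DV({c_j.disease_id}) = 0"
        )
    shared = set(c_i.values) & set(c_j.values)
    return sum(c_i.values[t] + c_j.values[t] for t in shared) / denom


def semantic_matrix(
    dag_forest: Mapping[str, DiseaseDAG],
    params: SemanticParams = SemanticParams(),
    model: int = 1,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over all diseases in the forest."""
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    labels = list(dag_forest)
    if model == 1:
        contribs = {d: contributions_model1(dag_forest[d], params) for d in labels}
    else:
        contribs = contributions_model2(dag_forest, params)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = semantic_similarity(contribs[labels[i]], contribs[labels[j]])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(labels, values, kind=f"Sim{model}")
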