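"""Disease semantic similarity from ontology DAGs.

Two sibling cancers under a shared parent term are compared with an
unrelated disease, using both the decay-based (model 1) and the
specificity-based (model 2) similarity models.
"""

from mlmda import DiseaseDAG, SemanticParams, semantic_matrix

# a tiny ontology: neoplasms -> {lung cancer, breast cancer}; asthma apart
forest = {
    "lung cancer": DiseaseDAG(
        "lung cancer",
        frozenset({"lung cancer", "neoplasms"}),
        frozenset({("neoplasms", "lung cancer")}),
    ),
    "breast cancer": DiseaseDAG(
        "breast cancer",
        frozenset({"breast cancer", "neoplasms"}),
        frozenset({("neoplasms", "breast cancer")}),
    ),
    "asthma": DiseaseDAG(
        "asthma",
        frozenset({"asthma", "lung diseases"}),
        frozenset({("lung diseases", "asthma")}),
    ),
}

for model in (1, 2):
    sim = semantic_matrix(forest, SemanticParams(delta=0.5), model=model)
    print(f"model {model}:")
    print(sim.to_frame().round(3).to_string())
    print()

# With delta=0.5, model 1 gives the two cancers similarity
# (0.5 + 0.5) / (1.5 + 1.5) = 1/3: they share only the parent term, which
# contributes 0.5 to each.  Asthma shares no term with either cancer, so
# its off-diagonal similarities are 0.  Model 2 weighs shared terms by how
# rare they are across all three DAGs instead of by DAG depth.
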