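"""Ranked candidate miRNAs for one disease.

After training on all known associations, every miRNA not yet linked to
the chosen disease is scored; the head of the list is the model's
prediction of missing associations.
"""

from mlmda import (
    EvalConfig,
    FixtureConfig,
    fit_full_model,
    generate_fixture,
    rank_candidates,
)

fx = generate_fixture(FixtureConfig(n_diseases=24, n_mirnas=32, n_blocks=2, seed=1))
model = fit_full_model(fx.assoc, fx.dag_forest, fx.records, None, EvalConfig(seed=1))

disease = fx.assoc.disease_ids[0]
block = fx.disease_blocks[0]
same_block = {
    m for m, b in zip(fx.assoc.mirna_ids, fx.mirna_blocks) if b == block
}
top = rank_candidates(model, disease).top(10)
print(f"top 10 candidates for {disease} (block {block}):")
for mirna, score in top:
    mark = "*" if mirna in same_block else " "
    print(f"  {mark} {mirna}  {score:.3f}")
print("(* = miRNA from the disease's own planted block)")

# Candidates from the disease's own co-association block should dominate
# the head of the ranking: they are the pairs the generator planted as
# plausible-but-unobserved.
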