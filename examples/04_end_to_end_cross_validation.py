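"""Fivefold cross-validation of the full pipeline on synthetic data.

A planted-block fixture (co-association blocks mirrored in the ontology
and the sequences) is generated, the complete feature pipeline is run,
and a random forest is evaluated with stratified fivefold CV, including
a label-permutation null.
"""

from mlmda import EvalConfig, FixtureConfig, crossvalidate, generate_fixture

fx = generate_fixture(FixtureConfig(n_diseases=40, n_mirnas=48, n_blocks=4, seed=0))
print(
    f"fixture: {fx.assoc.nd} diseases x {fx.assoc.nm} miRNAs, "
    f"{int(fx.assoc.values.sum())} known associations"
)

cfg = EvalConfig(seed=0)
report = crossvalidate(fx.assoc, fx.dag_forest, fx.records, None, cfg)
for name, stats in report.summary().items():
    print(f"  {name:9s} {stats['mean']:.4f} +/- {stats['std']:.4f}")

null = crossvalidate(
    fx.assoc, fx.dag_forest, fx.records, None, cfg, permute_labels=True
)
print(f"  permutation-null AUC {null.mean('auc'):.4f}")

# The planted block structure is recoverable (AUC well above 0.5) while
# the permuted labels collapse to chance, showing the signal comes from
# the data and not from a leak in the evaluation protocol.
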