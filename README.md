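# mlmda

Machine-learning prediction of miRNA–disease associations from
heterogeneous similarity, sequence information, autoencoder feature
compression and a random-forest classifier.

## The problem

MicroRNAs regulate gene expression, and individual miRNAs are implicated
in specific human diseases; experimentally confirming each association is
slow, so computational ranking of candidate disease–miRNA pairs guides
which experiments to run.  The guiding assumption is that functionally
similar diseases associate with similar miRNAs.  This package builds a
pair classifier from four information sources:

- **Disease semantic similarity** from ontology DAGs.  With decay factor
  Δ, model 1 scores each ancestor term *t* of disease *D* as
  `D1_D(D) = 1`, `D1_D(t) = max{Δ·D1_D(t′) : t′ child of t}`, the
  semantic value is `DV(D) = Σ_t D1_D(t)`, and
  `Sim1(i,j) = Σ_{t∈T_i∩T_j}(D1_i(t)+D1_j(t)) / (DV_i+DV_j)`.
  Model 2 instead scores a term by its specificity,
  `D2(t) = log(1 + df(t)/n)`, with `df(t)` the number of disease DAGs
  containing *t*.
- **Gaussian interaction-profile (GIP) kernels** on the binary adjacency
  matrix *A* (diseases × miRNAs):
  `KD(a,b) = exp(−γ_d‖IP(a)−IP(b)‖²)`, with
  `γ_d = γ′_d / mean_i ‖IP(i)‖²`; rows of *A* are disease profiles,
  columns miRNA profiles.
- **Integrated similarities**: `SD = (Sim1+Sim2)/2` where both diseases
  have DAGs, else `KD`; `SM = FS` where a functional-similarity matrix
  covers both miRNAs, else `KM`.
- **Sequence descriptors**: each precursor sequence becomes a one-hot
  64 × (L−2) matrix of overlapping 3-mers, reduced by truncated SVD to
  64 × 5 and flattened to a fixed 320-vector `F_seq`.

For a pair (d, m), the disease's SD row, the miRNA's SM column and
`F_seq` are min-max scaled and compressed by three single-hidden-layer
autoencoders to 16, 16 and 32 dimensions; their concatenation
`F = (F_sim′, F_seq′)` (64-dim) feeds a 100-tree random forest trained on
the known associations plus an equal number of uniformly sampled
unobserved pairs, evaluated with stratified fivefold cross-validation.

## Worked example

No downloads are needed: `mlmda.simulate` generates synthetic inputs with
the statistical structure the method assumes (co-association blocks
mirrored in the ontology and the sequences).

```python
from mlmda import EvalConfig, FixtureConfig, crossvalidate, generate_fixture

fx = generate_fixture(FixtureConfig(n_diseases=40, n_mirnas=48, n_blocks=4, seed=0))
report = crossvalidate(fx.assoc, fx.dag_forest, fx.records, None, EvalConfig(seed=0))
for name, stats in report.summary().items():
    print(f"{name:9s} {stats['mean']:.4f} +/- {stats['std']:.4f}")
```

prints

```
accuracy  0.8460 +/- 0.0108
recall    0.8635 +/- 0.0342
precision 0.8356 +/- 0.0236
f1        0.8485 +/- 0.0118
auc       0.8901 +/- 0.0274
```

i.e. on a 40 × 48 fixture with 315 planted associations the classifier
separates held-out known pairs from sampled unobserved pairs with mean
ROC AUC 0.89 across the five folds, while the same pipeline on permuted
labels drops to chance (≈ 0.52) — the signal comes from the planted
structure, not from the evaluation protocol.  The `examples/` directory
has one short script per capability (semantic similarity, GIP kernel,
sequence descriptor, end-to-end CV, candidate ranking), and the `mlmda`
command exposes the same stages for shell use (`mlmda simulate`,
`mlmda semantic`, `mlmda gip`, `mlmda seqfeat`, `mlmda run`, ...).

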