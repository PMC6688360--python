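# Methods

## Overview

The package scores disease–miRNA pairs by combining four views of the
data — disease ontology structure, network interaction profiles, an
optional external functional-similarity matrix, and precursor sequence
composition — into a single 64-dimensional feature vector per pair, and
classifying pairs with a random forest.  The pipeline has five stages:
(1) adjacency matrix and positive/negative sets, (2) similarity
matrices, (3) sequence descriptors, (4) autoencoder compression,
(5) classification and evaluation.

## Similarity construction

**Semantic model 1** walks each disease's ontology DAG: the disease term
contributes 1 and each ancestor contributes `Δ^k` with `k` its shortest
downward distance to the disease (the recursion takes the max over a
term's children *inside that disease's DAG*, not the global ontology).
`Δ = 0.5` by default — the conventional choice in hierarchy-based
disease-similarity work; larger Δ flattens the hierarchy, Δ → 0 reduces
similarity to term identity.  **Semantic model 2** scores a term by
`log(1 + df(t)/n)` where `df(t)` counts the disease DAGs containing the
term and `n` is the number of diseases; rare (specific) terms score low
absolutely but *shared* rare terms dominate the pairwise ratio.  The
logarithm is natural by default and configurable.  In both models the
pairwise similarity normalises the shared-term contribution mass by the
sum of the two semantic values, so self-similarity is 1.

**GIP kernels** use bandwidth `γ = γ′ / mean‖IP‖²` with `γ′ = 1` for
both axes (the convention of the kernel's original formulation).  The
normalisation makes the kernel scale-free in network density: doubling
`γ′` squares every off-diagonal entry.

**Integration** is branch-wise, not weighted: the semantic mean where
ontology information exists, the GIP kernel elsewhere; the functional
similarity matrix, when provided, overrides the miRNA kernel on its
coverage.  Disease semantic coverage is defined as "the disease has a
DAG"; both semantic matrices share that coverage set by construction.

## Sequence descriptor

A length-L precursor yields a 64 × (L−2) matrix whose column *j* one-hot
encodes the 3-mer at position *j* (lexicographic order, A<C<G<U).  The
positional reading (rather than a plain 64-vector of 3-mer counts) is
what produces a matrix whose truncated SVD is meaningful; the embedding
kept is `U_r Σ_r` (rank 5), i.e. the k-mer-row geometry scaled by the
singular values, and the positional factor `V` is discarded.  Sign
ambiguity is fixed by forcing each singular vector's largest-magnitude
entry positive, making descriptors bit-reproducible.  Sequences shorter
than the rank (or rank-deficient matrices) are zero-padded so the
flattened descriptor is always 64·5 = 320 long.

## Autoencoder compression

Three separate single-hidden-layer autoencoders (sigmoid encoder and
decoder, `σ(x) = 1/(1+e^{−x})`) compress the SD row (nd → 16), the SM
column (nm → 16) and the sequence descriptor (320 → 32).  Inputs are
min-max scaled per feature to [0, 1], the sigmoid's output range, with
the scaler fit on training data only.  Training minimises the mean (over
samples) summed squared reconstruction error by full-batch gradient
descent with classical momentum (defaults: 200 epochs, learning rate
1.0, momentum 0.9, Glorot-uniform initialisation from a fixed seed).
Momentum matters here: plain small-step descent at this epoch budget
leaves the larger blocks with near-total unexplained variance, i.e. an
uninformative bottleneck; with the defaults the disease/miRNA blocks
reconstruct to within a few percent of their variance.  Set
`momentum=0` for plain descent, `activation="linear"` for analytical
checks.  All training is deterministic given the seed.

## Sampling, classification and evaluation

Negatives are drawn uniformly without replacement from the unobserved
cells of the adjacency matrix, by default as many as the positives
(balanced 1:1).  The classifier is a 100-tree random forest
(sqrt-features per split, unlimited depth, fixed seed); threshold 0.5
defines the confusion-matrix metrics, and AUC is the trapezoidal area
under the held-out ROC.

Cross-validation is stratified fivefold at the pair level.  Scalers and
autoencoders are always refit on the training fold only.  Two protocols
are provided for the similarity matrices:

- **default**: KD/KM are computed once from the full known adjacency
  before folding.  This matches the method's published evaluation
  protocol, in which the similarity matrices are inputs to CV.
- **`mask_held_out=True`**: KD/KM are recomputed per fold with the
  held-out fold's known associations zeroed, so test labels cannot reach
  the features through the interaction profiles.

On the default synthetic fixture the two differ by under 0.01 mean AUC
(the per-pair information carried by a single adjacency entry is heavily
diluted by kernel averaging and autoencoder compression), but the masked
protocol is the conservative choice for method comparisons.

Candidate ranking trains on all known associations plus sampled
negatives, scores every miRNA not linked to the query disease, and sorts
by descending probability with lexicographic identifier tie-breaks.

## Synthetic data

The generator plants one latent block structure across all modalities:
diseases and miRNAs are partitioned into `n_blocks` groups; within-block
pairs associate with probability 0.6 versus a 0.02 background;
same-block diseases hang under a shared ancestor chain (depth 2–4) in
the ontology; same-block sequences (uniform random, 60–90 nt,
precursor-like) carry a block-specific 3-mer substituted at rate 0.3 per
codon-aligned position; the optional functional-similarity matrix is a
noisy block indicator.  Defaults are 60 diseases × 80 miRNAs in 4
blocks.  Everything is deterministic per seed, and written fixtures are
byte-identical across runs.

What the fixture does *not* emulate: the heavy-tailed degree
distributions of real association databases, correlated (non-iid)
association noise, ontology DAGs with multiple parents per term, and
sequence homology families.  Passing tests therefore demonstrate that
the pipeline recovers planted block-level structure and that its
numerical contracts hold — not that real-database performance figures
transfer.

A useful consequence of the iid-within-block design is a computable
performance ceiling: given block membership, within-block labels are
independent coin flips, so no leakage-free classifier can rank a
within-block unobserved pair against a within-block positive better than
chance.  With the default parameters this bounds the achievable
fivefold-CV AUC at ≈ 0.88–0.90 (observed: ≈ 0.885 masked, ≈ 0.896
default protocol, mean over ten seeds), with the permutation null at
≈ 0.5.  Stronger numbers on this fixture would indicate a leak, not a
better method.

## Numerical and design notes

- All similarity matrices are exactly symmetrised by construction and
  validated on read; CSV output uses 6 significant digits.
- Identifiers are lowercased on read everywhere, so association tables,
  FASTA headers and matrix labels join by exact string match; miRNAs
  without a precursor sequence are dropped with a logged warning.
- Degenerate inputs fail loudly: all-zero interaction profiles (kernel
  bandwidth undefined), DAG cycles, sequences shorter than k, folds
  missing a class, negative-sample requests exceeding the unobserved
  grid.
- The per-pair feature assembly is a pure function of its inputs; the
  whole pipeline is deterministic given the config seed (the run
  manifest records the config hash and seed).
- Problem sizes used in the shipped checks (fixtures of 18–80 entities,
  three to ten replicates, 50–200 autoencoder epochs) were chosen so the
  full suite runs comfortably on a laptop-class single core while
  keeping every statistical margin (recovery vs. null) wide.

## Known limitations

- The blockwise autoencoders are compressors, not denoisers; no
  stacked/denoising/variational variants.
- Ranked predictions are not calibrated probabilities; only the order is
  meaningful.
- Entity-level (leave-disease-out) cross-validation is not implemented;
  folds are pair-level, so performance estimates apply to completing a
  partially observed network, not to diseases with no known miRNA.
- The DAG reader takes a flat parent→child edge list; ontology formats
  with tree-number encodings must be flattened upstream.
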