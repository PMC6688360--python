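"""Synthetic fixture generator with planted block structure.

The generator embodies the core modelling assumption — functionally
similar diseases associate with similar miRNAs — by partitioning diseases
and miRNAs into co-association blocks: within-block pairs associate with
high probability and cross-block pairs with a low background rate.  The
same block structure is planted in every data modality the pipeline
consumes: diseases of one block share a distinct ancestor chain in the
ontology forest, miRNA precursor sequences of one block are enriched for
a block-specific 3-mer motif, and the optional functional-similarity
matrix is a noisy block indicator.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG, SequenceRecord, SimilarityMatrix
from .io import write_associations, write_similarity_csv

__all__ = ["FixtureConfig", "Fixture", "generate_fixture", "write_fixture"]

_ALPHABET = "ACGU"


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and signal strength of the planted-block fixture.

    Defaults are sized so that a desk-scale run exhibits the structure the
    method exploits: 60 diseases x 80 miRNAs in 4 blocks, within-block
    association probability 0.6 against a 0.02 background, precursor-like
    sequence lengths of 60-90 nt, and a motif substitution rate of 0.3.
    """

    n_diseases: int = 60
    n_mirnas: int = 80
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.6
    background_assoc_prob: float = 0.02
    seq_length_range: tuple[int, int] = (60, 90)
    motif_rate: float = 0.3
    dag_depth_range: tuple[int, int] = (2, 4)
    with_fs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_mirnas < 1 or self.n_blocks < 1:
            raise ValueError("entity and block counts must be positive")
        if self.n_blocks > min(self.n_diseases, self.n_mirnas):
            raise ValueError("more blocks than entities")
        for p in (self.within_block_assoc_prob, self.background_assoc_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.within_block_assoc_prob <= self.background_assoc_prob:
            raise ValueError(
                "within-block probability must exceed the background rate"
            )


@dataclass
class Fixture:
    """A complete synthetic input set plus its generating block labels."""

    assoc: AssociationMatrix
    dag_forest: dict[str, DiseaseDAG]
    records: list[SequenceRecord]
    fs: Optional[SimilarityMatrix]
    disease_blocks: np.ndarray
    mirna_blocks: np.ndarray
    dag_edges: list[tuple[str, str]]


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous, nearly equal-sized block labels 0..n_blocks-1."""
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n, n_blocks + 1).astype(int)))


def _block_motifs(n_blocks: int, rng: np.random.Generator) -> list[str]:
    """Distinct 3-mers, one per block."""
    all_triples = ["".join(t) for t in product(_ALPHABET, repeat=3)]
    picks = rng.choice(len(all_triples), size=n_blocks, replace=False)
    return [all_triples[i] for i in picks]


def generate_fixture(cfg: FixtureConfig = FixtureConfig()) -> Fixture:
    """Generate associations, ontology forest, sequences and optional FS."""
    rng = np.random.default_rng(cfg.seed)
    d_blocks = _block_assignment(cfg.n_diseases, cfg.n_blocks)
    m_blocks = _block_assignment(cfg.n_mirnas, cfg.n_blocks)
    disease_ids = [f"disease{i:03d}" for i in range(cfg.n_diseases)]
    mirna_ids = [f"mir{i:03d}" for i in range(cfg.n_mirnas)]

    # adjacency: within-block vs background Bernoulli rates
    same_block = d_blocks[:, None] == m_blocks[None, :]
    probs = np.where(
        same_block, cfg.within_block_assoc_prob, cfg.background_assoc_prob
    )
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    assoc = AssociationMatrix(values, disease_ids, mirna_ids)

    # ontology forest: one root, per-block ancestor chain, per-disease leaf
    lo, hi = cfg.dag_depth_range
    edges: list[tuple[str, str]] = []
    block_leaf: dict[int, str] = {}
    for b in range(cfg.n_blocks):
        depth = int(rng.integers(lo, hi + 1))
        chain = [f"branch{b}_{lvl}" for lvl in range(depth)]
        edges.append(("root", chain[0]))
        edges.extend(zip(chain[:-1], chain[1:]))
        block_leaf[b] = chain[-1]
    for d, b in zip(disease_ids, d_blocks):
        edges.append((block_leaf[int(b)], d))
    # keep DAGs for the diseases themselves, not internal ontology terms
    dag_forest = {
        d: g for d, g in _forest_from_edges(edges).items() if d in set(disease_ids)
    }

    # sequences: uniform background with a planted block motif
    motifs = _block_motifs(cfg.n_blocks, rng)
    records: list[SequenceRecord] = []
    for m, b in zip(mirna_ids, m_blocks):
        length = int(rng.integers(cfg.seq_length_range[0], cfg.seq_length_range[1] + 1))
        seq = list(rng.choice(list(_ALPHABET), size=length))
        motif = motifs[int(b)]
        for start in range(0, length - 2, 3):
            if rng.random() < cfg.motif_rate:
                seq[start : start + 3] = motif
        records.append(SequenceRecord(m, "".join(seq)))

    fs = None
    if cfg.with_fs:
        base = np.where(m_blocks[:, None] == m_blocks[None, :], 0.9, 0.1)
        noise = rng.normal(0, 0.05, size=base.shape)
        sym = np.clip(base + (noise + noise.T) / 2, 0.0, 1.0)
        np.fill_diagonal(sym, 1.0)
        fs = SimilarityMatrix(mirna_ids, sym, kind="FS")

    return Fixture(assoc, dag_forest, records, fs, d_blocks, m_blocks, edges)


def _forest_from_edges(edges: list[tuple[str, str]]) -> dict[str, DiseaseDAG]:
    """Ancestor closure per term from a (parent, child) edge list."""
    parents: dict[str, set[str]] = {}
    for p, c in edges:
        parents.setdefault(c, set()).add(p)
        parents.setdefault(p, set())
    forest: dict[str, DiseaseDAG] = {}
    for term in parents:
        closure = {term}
        stack = [term]
        while stack:
            node = stack.pop()
            for p in parents[node]:
                if p not in closure:
                    closure.add(p)
                    stack.append(p)
        closure_edges = frozenset(
            (p, c) for p, c in edges if p in closure and c in closure
        )
        forest[term] = DiseaseDAG(term, frozenset(closure), closure_edges)
    return forest


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Persist the fixture as TSV/FASTA/CSV; byte-identical for one seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "dag_edges": outdir / "dag_edges.tsv",
        "sequences": outdir / "sequences.fa",
    }
    write_associations(fixture.assoc, paths["associations"])
    with open(paths["dag_edges"], "w") as fh:
        fh.write("parent\tchild\n")
        for p, c in sorted(set(fixture.dag_edges)):
            fh.write(f"{p}\t{c}\n")
    with open(paths["sequences"], "w") as fh:
        for rec in fixture.records:
            fh.write(f">{rec.mirna_id}\n{rec.sequence}\n")
    if fixture.fs is not None:
        paths["fs"] = outdir / "functional_similarity.csv"
        write_similarity_csv(fixture.fs, paths["fs"])
    return paths
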