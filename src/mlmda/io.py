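"""Readers and writers for the standard input formats.

Associations come as a two-column TSV of (disease_id, mirna_id) pairs, the
disease ontology as a TSV edge list of (parent, child) term pairs, precursor
sequences as FASTA, and all similarity / feature matrices as labelled CSV.
Identifiers are lowercased on read so the association table, FASTA headers
and similarity-matrix labels can be joined by exact string match.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import AssociationMatrix, DiseaseDAG, SequenceRecord, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_associations",
    "write_associations",
    "read_dag_forest",
    "read_fasta",
    "read_similarity_csv",
    "write_similarity_csv",
    "match_sequences",
]

#: column headings recognised (case-insensitively) as a header line
_HEADER_TOKENS = {"disease", "disease_id", "mirna", "mirna_id", "parent", "child"}


def _parse_pair_lines(path: Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            a, b = (f.strip().lower() for f in fields)
            if lineno == 1 and {a, b} & _HEADER_TOKENS:
                continue
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"{path}: no pairs found")
    return pairs


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a TSV of (disease_id, mirna_id) pairs into an adjacency matrix.

    Rows are diseases, columns miRNAs, both in first-appearance order.
    Duplicate pairs collapse to a single 1.
    """
    pairs = _parse_pair_lines(Path(path))
    diseases: dict[str, int] = {}
    mirnas: dict[str, int] = {}
    for d, m in pairs:
        diseases.setdefault(d, len(diseases))
        mirnas.setdefault(m, len(mirnas))
    values = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for d, m in pairs:
        values[diseases[d], mirnas[m]] = 1
    return AssociationMatrix(values, list(diseases), list(mirnas))


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the association matrix back out as a pair-per-line TSV."""
    with open(path, "w") as fh:
        fh.write("disease_id\tmirna_id\n")
        for d, m in assoc.pairs():
            fh.write(f"{d}\t{m}\n")


def read_dag_forest(path: str | Path) -> dict[str, DiseaseDAG]:
    """Read a (parent, child) TSV edge list into per-term ancestor DAGs.

    For every term in the file, the returned DAG holds the term plus all
    terms reachable by following child -> parent links, with the edges
    restricted to that closure.  Raises on cycles, naming one member.
    """
    edges = _parse_pair_lines(Path(path))
    graph = nx.DiGraph(edges)  # parent -> child
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"{path}: ontology contains a cycle through {cycle[0][0]!r}")
    forest: dict[str, DiseaseDAG] = {}
    for term in graph.nodes:
        ancestors = nx.ancestors(graph, term) | {term}
        closure_edges = frozenset(
            (p, c) for p, c in graph.edges if p in ancestors and c in ancestors
        )
        forest[term] = DiseaseDAG(term, frozenset(ancestors), closure_edges)
    return forest


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read precursor sequences from FASTA, uppercasing and mapping T -> U.

    The header token up to the first whitespace (lowercased) is the miRNA
    identifier.  Any character outside {A, C, G, U, T} is an error naming
    the record and position.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        for pos, ch in enumerate(seq):
            if ch not in "ACGU":
                raise ValueError(
                    f"{path}: record {rec.id!r}: invalid character {ch!r} "
                    f"at position {pos}"
                )
        records.append(SequenceRecord(rec.id.lower(), seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_similarity_csv(path: str | Path, kind: str = "") -> SimilarityMatrix:
    """Read a labelled square CSV (header row + index column)."""
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str).str.lower()
    frame.columns = frame.columns.astype(str).str.lower()
    return SimilarityMatrix.from_frame(frame, kind)


def write_similarity_csv(matrix: SimilarityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, float_format="%.6g")


def match_sequences(
    assoc: AssociationMatrix, records: list[SequenceRecord]
) -> tuple[AssociationMatrix, dict[str, SequenceRecord]]:
    """Drop miRNAs without a precursor sequence, with a logged warning.

    Mirrors the screening step in which association pairs whose miRNA has
    no precursor record are removed before the adjacency matrix is built.
    """
    by_id = {r.mirna_id: r for r in records}
    missing = [m for m in assoc.mirna_ids if m not in by_id]
    if missing:
        logger.warning(
            "dropping %d miRNA(s) without a sequence: %s",
            len(missing),
            ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )
        assoc = assoc.subset_mirnas([m for m in assoc.mirna_ids if m in by_id])
    return assoc, {m: by_id[m] for m in assoc.mirna_ids}
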