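"""Core in-memory containers shared across the pipeline.

The method operates on three kinds of objects: a binary disease x miRNA
adjacency matrix (the association network), per-disease ontology DAGs
(each disease together with its ancestor terms), and labelled square
similarity matrices.  All of them are thin wrappers around numpy arrays
with ordered identifier lists, so that every downstream stage can align
entities by name instead of by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "SequenceRecord",
    "SimilarityMatrix",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A precursor miRNA sequence over the RNA alphabet {A, C, G, U}."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.mirna_id!r}")
        for pos, ch in enumerate(self.sequence):
            if ch not in "ACGU":
                raise ValueError(
                    f"record {self.mirna_id!r}: invalid character {ch!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease with its ancestor closure in the disease ontology.

    ``ancestors`` contains the disease itself plus every term reachable by
    walking child -> parent edges; ``edges`` is the set of (parent, child)
    pairs restricted to that closure.
    """

    disease_id: str
    ancestors: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.disease_id not in self.ancestors:
            raise ValueError(
                f"DAG for {self.disease_id!r} must contain the disease itself"
            )
        for parent, child in self.edges:
            if parent not in self.ancestors or child not in self.ancestors:
                raise ValueError(
                    f"DAG for {self.disease_id!r}: edge ({parent!r}, {child!r}) "
                    "leaves the ancestor closure"
                )

    def children_of(self, term: str) -> set[str]:
        """Terms that are direct children of ``term`` inside this DAG."""
        return {c for p, c in self.edges if p == term}


@dataclass
class AssociationMatrix:
    """Binary adjacency matrix A: rows are diseases, columns are miRNAs.

    Row *a* is the interaction profile of disease d(a); column *a* is the
    interaction profile of miRNA m(a).
    """

    values: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]
    _d_index: dict[str, int] = field(init=False, repr=False)
    _m_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        nd, nm = self.values.shape
        if nd != len(self.disease_ids) or nm != len(self.mirna_ids):
            raise ValueError("matrix shape does not match identifier lists")
        if len(set(self.disease_ids)) != nd:
            raise ValueError("duplicate disease identifiers")
        if len(set(self.mirna_ids)) != nm:
            raise ValueError("duplicate miRNA identifiers")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self._d_index = {d: i for i, d in enumerate(self.disease_ids)}
        self._m_index = {m: j for j, m in enumerate(self.mirna_ids)}

    @property
    def nd(self) -> int:
        return self.values.shape[0]

    @property
    def nm(self) -> int:
        return self.values.shape[1]

    def disease_index(self, disease_id: str) -> int:
        try:
            return self._d_index[disease_id]
        except KeyError:
            raise KeyError(f"unknown disease {disease_id!r}") from None

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self._m_index[mirna_id]
        except KeyError:
            raise KeyError(f"unknown miRNA {mirna_id!r}") from None

    def pairs(self) -> list[tuple[str, str]]:
        """All (disease_id, mirna_id) pairs with A = 1, in row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.disease_ids[i], self.mirna_ids[j]) for i, j in zip(rows, cols)]

    def subset_mirnas(self, keep: Sequence[str]) -> "AssociationMatrix":
        """Restrict the matrix to the given miRNAs, preserving column order."""
        keep_set = set(keep)
        cols = [j for j, m in enumerate(self.mirna_ids) if m in keep_set]
        return AssociationMatrix(
            self.values[:, cols],
            list(self.disease_ids),
            [self.mirna_ids[j] for j in cols],
        )

    def mask_pairs(self, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Return a copy with the given pairs zeroed (for fold-wise profiles)."""
        values = self.values.copy()
        for d, m in pairs:
            values[self.disease_index(d), self.mirna_index(m)] = 0
        return AssociationMatrix(values, list(self.disease_ids), list(self.mirna_ids))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over its labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in similarity matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[self._index[a], self._index[b]])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        return self._index[label]

    def row(self, label: str) -> np.ndarray:
        return self.values[self._index[label]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "") -> "SimilarityMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column labels differ")
        return cls(list(map(str, frame.index)), frame.to_numpy(dtype=float), kind)


def check_same_labels(*matrices: SimilarityMatrix) -> list[str]:
    """Ensure all matrices share one label ordering; return it."""
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError(
                f"label mismatch between {matrices[0].kind or 'matrix'} "
                f"and {m.kind or 'matrix'}"
            )
    return labels


def dag_forest_coverage(dag_forest: Mapping[str, DiseaseDAG]) -> frozenset[str]:
    """Diseases that possess an ontology DAG (semantic coverage set)."""
    return frozenset(dag_forest)
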