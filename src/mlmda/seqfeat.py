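"""Fixed-length sequence descriptors from k-mer position matrices.

A precursor sequence of length L is first expanded into a sparse 4^k x
(L - k + 1) matrix whose column j is the one-hot indicator of the k-mer
starting at position j (k-mers ordered lexicographically with A < C < G <
U).  Truncated SVD then maps this variable-width matrix to a fixed
4^k x r embedding U_r * Sigma_r — the k-mer rows are the entities carried
forward, the positional columns are collapsed — and row-major flattening
yields the final descriptor of length 4^k * r (320 for k=3, r=5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import SequenceRecord

__all__ = [
    "KmerMatrix",
    "SequenceDescriptor",
    "kmer_index",
    "kmer_matrix",
    "svd_reduce",
    "descriptor_table",
]

_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer under A < C < G < U."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(_ALPHABET, repeat=k)]


@dataclass(frozen=True)
class KmerMatrix:
    """One-hot k-mer-by-position matrix of a single sequence."""

    mirna_id: str
    M: np.ndarray
    k: int


@dataclass(frozen=True)
class SequenceDescriptor:
    """SVD-reduced k-mer embedding and its flattened feature vector."""

    mirna_id: str
    reduced: np.ndarray
    f_seq: np.ndarray


def kmer_matrix(seq: SequenceRecord, k: int = 3) -> KmerMatrix:
    """Build the 4^k x (L - k + 1) positional one-hot matrix."""
    L = len(seq.sequence)
    if L < k:
        raise ValueError(
            f"sequence {seq.mirna_id!r} is shorter than k={k} ({L} nt)"
        )
    n_cols = L - k + 1
    M = np.zeros((4**k, n_cols))
    for j in range(n_cols):
        M[kmer_index(seq.sequence[j : j + k]), j] = 1.0
    return KmerMatrix(seq.mirna_id, M, k)


def _fix_signs(U: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Force each singular vector's largest-magnitude entry positive."""
    U = U.copy()
    for i in range(U.shape[1]):
        col = U[:, i]
        if col[np.argmax(np.abs(col))] < 0:
            U[:, i] = -col
    return U


def svd_reduce(km: KmerMatrix, rank: int = 5) -> SequenceDescriptor:
    """Reduce the positional matrix to 4^k x rank via truncated SVD.

    The embedding is U_r * Sigma_r (left singular vectors scaled by their
    singular values); components beyond the matrix rank, or beyond its
    column count, are zero columns, so the flattened descriptor always has
    length 4^k * rank.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    U, s, _ = np.linalg.svd(km.M, full_matrices=False)
    r = min(rank, len(s))
    U = _fix_signs(U[:, :r], s[:r])
    reduced = np.zeros((km.M.shape[0], rank))
    reduced[:, :r] = U * s[:r]
    return SequenceDescriptor(km.mirna_id, reduced, reduced.ravel(order="C"))


def descriptor_table(
    records: Iterable[SequenceRecord] | Mapping[str, SequenceRecord],
    k: int = 3,
    rank: int = 5,
) -> pd.DataFrame:
    """Per-miRNA descriptors as a DataFrame (rows = miRNAs, 4^k * rank cols)."""
    if isinstance(records, Mapping):
        records = list(records.values())
    rows = {}
    for rec in records:
        rows[rec.mirna_id] = svd_reduce(kmer_matrix(rec, k), rank).f_seq
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"f{i + 1}" for i in range(4**k * rank)]
    return frame
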