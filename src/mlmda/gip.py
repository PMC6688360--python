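"""Gaussian interaction-profile (GIP) kernel similarity.

Two diseases are similar if they associate with similar miRNA sets (and
vice versa): the kernel is exp(-gamma * ||IP(a) - IP(b)||^2) on the binary
interaction profiles (rows of the adjacency matrix for diseases, columns
for miRNAs), with the bandwidth normalised by the mean squared profile
norm, gamma = gamma' / mean_i ||IP(i)||^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import AssociationMatrix, SimilarityMatrix

__all__ = ["GipParams", "gip_matrix", "gip_bandwidth"]


@dataclass(frozen=True)
class GipParams:
    """Original (pre-normalisation) kernel bandwidth gamma'."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")


def _profiles(assoc: AssociationMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "diseases":
        return assoc.values.astype(float), list(assoc.disease_ids)
    if axis == "mirnas":
        return assoc.values.T.astype(float), list(assoc.mirna_ids)
    raise ValueError("axis must be 'diseases' or 'mirnas'")


def gip_bandwidth(
    assoc: AssociationMatrix, axis: str, params: GipParams = GipParams()
) -> float:
    """Normalised bandwidth gamma = gamma' / mean squared profile norm."""
    profiles, _ = _profiles(assoc, axis)
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0:
        raise ValueError(f"all {axis} profiles are zero; bandwidth undefined")
    return params.gamma_prime / mean_sq_norm


def gip_matrix(
    assoc: AssociationMatrix, axis: str, params: GipParams = GipParams()
) -> SimilarityMatrix:
    """GIP kernel matrix over diseases (rows of A) or miRNAs (columns)."""
    profiles, labels = _profiles(assoc, axis)
    gamma = gip_bandwidth(assoc, axis, params)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq_dists)
    np.fill_diagonal(values, 1.0)
    kind = "KD" if axis == "diseases" else "KM"
    return SimilarityMatrix(labels, values, kind=kind)
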