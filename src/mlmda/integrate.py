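"""Fusion of semantic/functional similarity with the GIP kernel.

The integrated disease similarity SD averages the two semantic models
where both diseases have an ontology DAG and falls back to the GIP kernel
elsewhere.  The integrated miRNA similarity SM prefers the functional
similarity matrix FS where both miRNAs are covered by it and falls back
to the GIP kernel elsewhere; without FS it is the GIP kernel itself.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .containers import SimilarityMatrix, check_same_labels

__all__ = ["integrate_disease", "integrate_mirna"]


def integrate_disease(
    sim1: SimilarityMatrix,
    sim2: SimilarityMatrix,
    kd: SimilarityMatrix,
    coverage: Iterable[str],
) -> SimilarityMatrix:
    """SD(a,b) = (Sim1 + Sim2) / 2 if both a, b have DAGs, else KD(a,b).

    ``kd`` fixes the output label ordering and must cover every disease;
    ``sim1``/``sim2`` share one label set covering (at least) ``coverage``.
    """
    check_same_labels(sim1, sim2)
    covered = set(coverage)
    missing = covered - set(sim1.labels)
    if missing:
        raise ValueError(f"semantic matrices missing covered diseases: {missing}")
    values = kd.values.copy()
    cov_idx = [i for i, lab in enumerate(kd.labels) if lab in covered]
    for i in cov_idx:
        for j in cov_idx:
            a, b = kd.labels[i], kd.labels[j]
            values[i, j] = 0.5 * (sim1[a, b] + sim2[a, b])
    return SimilarityMatrix(list(kd.labels), values, kind="SD")


def integrate_mirna(
    fs: Optional[SimilarityMatrix],
    km: SimilarityMatrix,
    coverage: Optional[Iterable[str]] = None,
) -> SimilarityMatrix:
    """SM(a,b) = FS(a,b) if both a, b are in FS, else KM(a,b).

    With ``fs`` absent the miRNA similarity is the GIP kernel unchanged.
    ``coverage`` defaults to the FS label set.
    """
    if fs is None:
        return SimilarityMatrix(list(km.labels), km.values.copy(), kind="SM")
    covered = set(coverage) if coverage is not None else set(fs.labels)
    missing = covered - set(fs.labels)
    if missing:
        raise ValueError(f"functional similarity missing covered miRNAs: {missing}")
    values = km.values.copy()
    cov_idx = [i for i, lab in enumerate(km.labels) if lab in covered]
    for i in cov_idx:
        for j in cov_idx:
            a, b = km.labels[i], km.labels[j]
            values[i, j] = fs[a, b]
    return SimilarityMatrix(list(km.labels), values, kind="SM")
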