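"""Labelled sample construction: negative sampling and feature assembly.

A positive sample is a confirmed disease-miRNA pair; negatives are drawn
uniformly without replacement from the unobserved cells of the adjacency
matrix, by default as many as there are positives (balanced classes).

Each pair (d, m) is described by three raw blocks — the disease's row of
the integrated disease similarity SD, the miRNA's column of the
integrated miRNA similarity SM, and the miRNA's fixed-length sequence
descriptor — which are min-max scaled to [0, 1] and compressed by three
block-wise autoencoders (disease 16, miRNA 16, sequence 32 under the
defaults), then concatenated into the final 64-dimensional vector
F = (F_sim', F_seq').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .autoencoder import AEModel, AETrainConfig, ae_encode, ae_train
from .containers import AssociationMatrix, SimilarityMatrix

__all__ = [
    "SampleFeature",
    "BlockEncoders",
    "sample_negatives",
    "fit_block_encoders",
    "assemble",
    "assemble_table",
]


@dataclass
class SampleFeature:
    """One labelled pair with its raw blocks and compressed feature vector."""

    disease_id: str
    mirna_id: str
    sd_row: np.ndarray
    sm_col: np.ndarray
    f_seq: np.ndarray
    f_sim_c: np.ndarray
    f_seq_c: np.ndarray
    f: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if len(self.f) != len(self.f_sim_c) + len(self.f_seq_c):
            raise ValueError("final vector must concatenate the two blocks")


def sample_negatives(
    assoc: AssociationMatrix,
    n: Optional[int] = None,
    seed: int = 0,
    exclude: Sequence[tuple[str, str]] = (),
) -> list[tuple[str, str]]:
    """Draw n distinct unobserved pairs uniformly without replacement.

    ``n`` defaults to the number of positives (balanced sampling); pairs
    in ``exclude`` are removed from the candidate pool as well.
    """
    flat_zero = np.flatnonzero(assoc.values.ravel() == 0)
    if exclude:
        banned = {
            assoc.disease_index(d) * assoc.nm + assoc.mirna_index(m)
            for d, m in exclude
        }
        flat_zero = np.array([i for i in flat_zero if i not in banned], dtype=int)
    if n is None:
        n = int(assoc.values.sum())
    if n > len(flat_zero):
        raise ValueError(
            f"requested {n} negatives but only {len(flat_zero)} unobserved "
            "pairs are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_zero, size=n, replace=False)
    return [
        (assoc.disease_ids[i // assoc.nm], assoc.mirna_ids[i % assoc.nm])
        for i in chosen
    ]


@dataclass
class BlockEncoders:
    """Per-block scalers and autoencoders fit on training samples only."""

    disease_scaler: MinMaxScaler
    mirna_scaler: MinMaxScaler
    seq_scaler: MinMaxScaler
    disease_ae: AEModel
    mirna_ae: AEModel
    seq_ae: AEModel


def _raw_blocks(
    pairs: Sequence[tuple[str, str]],
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    fseq_table: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d_rows = np.empty((len(pairs), len(sd.labels)))
    m_cols = np.empty((len(pairs), len(sm.labels)))
    seqs = np.empty((len(pairs), fseq_table.shape[1]))
    for i, (d, m) in enumerate(pairs):
        if d not in sd:
            raise KeyError(f"disease {d!r} missing from the SD matrix")
        if m not in sm:
            raise KeyError(f"miRNA {m!r} missing from the SM matrix")
        if m not in fseq_table.index:
            raise KeyError(f"miRNA {m!r} missing from the sequence table")
        d_rows[i] = sd.row(d)
        m_cols[i] = sm.row(m)  # symmetric: row == column profile
        seqs[i] = fseq_table.loc[m].to_numpy()
    return d_rows, m_cols, seqs


def fit_block_encoders(
    train_pairs: Sequence[tuple[str, str]],
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    fseq_table: pd.DataFrame,
    hidden_dims: tuple[int, int, int] = (16, 16, 32),
    cfg: AETrainConfig = AETrainConfig(),
) -> BlockEncoders:
    """Fit the three min-max scalers and autoencoders on training pairs."""
    d_rows, m_cols, seqs = _raw_blocks(train_pairs, sd, sm, fseq_table)
    scalers = [MinMaxScaler().fit(x) for x in (d_rows, m_cols, seqs)]
    blocks = [s.transform(x) for s, x in zip(scalers, (d_rows, m_cols, seqs))]
    aes = [
        ae_train(
            x,
            h,
            AETrainConfig(
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                momentum=cfg.momentum,
                seed=cfg.seed + off,
                activation=cfg.activation,
            ),
        )
        for off, (x, h) in enumerate(zip(blocks, hidden_dims))
    ]
    return BlockEncoders(*scalers, *aes)


def _encode_blocks(
    pairs: Sequence[tuple[str, str]],
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    fseq_table: pd.DataFrame,
    enc: BlockEncoders,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    d_rows, m_cols, seqs = _raw_blocks(pairs, sd, sm, fseq_table)
    d_c = ae_encode(enc.disease_ae, np.clip(enc.disease_scaler.transform(d_rows), 0, 1))
    m_c = ae_encode(enc.mirna_ae, np.clip(enc.mirna_scaler.transform(m_cols), 0, 1))
    s_c = ae_encode(enc.seq_ae, np.clip(enc.seq_scaler.transform(seqs), 0, 1))
    return d_rows, m_cols, seqs, np.hstack([d_c, m_c]), s_c


def assemble(
    pair: tuple[str, str],
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    fseq_table: pd.DataFrame,
    encoders: BlockEncoders,
    label: int = 1,
) -> SampleFeature:
    """Build the compressed feature vector for one pair."""
    d_rows, m_cols, seqs, f_sim_c, f_seq_c = _encode_blocks(
        [pair], sd, sm, fseq_table, encoders
    )
    f = np.concatenate([f_sim_c[0], f_seq_c[0]])
    return SampleFeature(
        pair[0], pair[1], d_rows[0], m_cols[0], seqs[0],
        f_sim_c[0], f_seq_c[0], f, label,
    )


def assemble_table(
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    fseq_table: pd.DataFrame,
    encoders: BlockEncoders,
) -> pd.DataFrame:
    """Vectorised assembly: one row per pair, feature columns plus label."""
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels must have equal length")
    _, _, _, f_sim_c, f_seq_c = _encode_blocks(pairs, sd, sm, fseq_table, encoders)
    F = np.hstack([f_sim_c, f_seq_c])
    frame = pd.DataFrame(F, columns=[f"f{i + 1}" for i in range(F.shape[1])])
    frame.insert(0, "disease_id", [p[0] for p in pairs])
    frame.insert(1, "mirna_id", [p[1] for p in pairs])
    frame["label"] = list(labels)
    return frame
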