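"""Random-forest prediction, fivefold cross-validation and ranking.

Cross-validation is performed at the pair level: positives (confirmed
associations) plus an equal number of uniformly sampled negatives are
split into stratified folds.  The min-max scalers and autoencoders are
always refit on the training fold only.  Under the standard protocol the
similarity matrices are built once from the full known adjacency; with
``EvalConfig(mask_held_out=True)`` the GIP kernels are additionally
recomputed per fold with the held-out associations zeroed out of the
adjacency, so that no test association can reach the features through
the interaction profiles.  AUC is the trapezoidal area under the ROC
curve of the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .autoencoder import AETrainConfig
from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    SequenceRecord,
    SimilarityMatrix,
    dag_forest_coverage,
)
from .features import (
    BlockEncoders,
    assemble_table,
    fit_block_encoders,
    sample_negatives,
)
from .gip import GipParams, gip_matrix
from .integrate import integrate_disease, integrate_mirna
from .semantics import SemanticParams, semantic_matrix
from .seqfeat import descriptor_table

__all__ = [
    "EvalConfig",
    "FoldMetrics",
    "CVReport",
    "PredictionList",
    "FittedModel",
    "train_rf",
    "compute_metrics",
    "crossvalidate",
    "fit_full_model",
    "rank_candidates",
]


@dataclass(frozen=True)
class EvalConfig:
    """Every tunable of the end-to-end pipeline with its default."""

    folds: int = 5
    n_trees: int = 100
    threshold: float = 0.5
    semantic: SemanticParams = SemanticParams()
    gip_diseases: GipParams = GipParams()
    gip_mirnas: GipParams = GipParams()
    kmer_k: int = 3
    svd_rank: int = 5
    hidden_dims: tuple[int, int, int] = (16, 16, 32)
    ae: AETrainConfig = AETrainConfig()
    seed: int = 42
    #: recompute the GIP kernels per fold with held-out associations zeroed
    #: (stricter than the standard protocol, which builds the similarity
    #: matrices once from the full known adjacency; see docs/methods.md)
    mask_held_out: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class FoldMetrics:
    accuracy: float
    recall: float
    precision: float
    f1: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
        }


@dataclass
class CVReport:
    """Per-fold metrics with their means and standard deviations."""

    per_fold: list[FoldMetrics]
    roc_points: list[tuple[np.ndarray, np.ndarray]]

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.per_fold]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(f, metric) for f in self.per_fold]))

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for metric in ("accuracy", "recall", "precision", "f1", "auc"):
            out[metric] = {"mean": self.mean(metric), "std": self.std(metric)}
        return out

    def to_json_dict(self) -> dict:
        return {
            "per_fold": [f.as_dict() for f in self.per_fold],
            "summary": self.summary(),
        }


@dataclass
class PredictionList:
    """Candidate miRNAs for one disease, sorted by descending score."""

    disease_id: str
    ranked: list[tuple[str, float]]

    def top(self, n: int) -> list[tuple[str, float]]:
        return self.ranked[:n]


def train_rf(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed: int = 42
) -> RandomForestClassifier:
    """Fit the random-forest classifier (sqrt features, unlimited depth)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> tuple[FoldMetrics, tuple[np.ndarray, np.ndarray]]:
    """Threshold metrics plus trapezoidal ROC AUC for one held-out fold."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    fpr, tpr, _ = roc_curve(y_true, scores)
    metrics = FoldMetrics(
        accuracy=accuracy_score(y_true, y_pred),
        recall=recall_score(y_true, y_pred, zero_division=0),
        precision=precision_score(y_true, y_pred, zero_division=0),
        f1=f1_score(y_true, y_pred, zero_division=0),
        auc=float(auc(fpr, tpr)),
    )
    return metrics, (fpr, tpr)


def _semantic_matrices(
    dag_forest: Mapping[str, DiseaseDAG], params: SemanticParams
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    return (
        semantic_matrix(dag_forest, params, model=1),
        semantic_matrix(dag_forest, params, model=2),
    )


def _fold_similarities(
    assoc_train: AssociationMatrix,
    sim1: SimilarityMatrix,
    sim2: SimilarityMatrix,
    coverage: frozenset[str],
    fs: Optional[SimilarityMatrix],
    cfg: EvalConfig,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    kd = gip_matrix(assoc_train, "diseases", cfg.gip_diseases)
    km = gip_matrix(assoc_train, "mirnas", cfg.gip_mirnas)
    sd = integrate_disease(sim1, sim2, kd, coverage & set(kd.labels))
    sm = integrate_mirna(fs, km)
    return sd, sm


def crossvalidate(
    assoc: AssociationMatrix,
    dag_forest: Mapping[str, DiseaseDAG],
    records: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    fs: Optional[SimilarityMatrix] = None,
    cfg: EvalConfig = EvalConfig(),
    permute_labels: bool = False,
) -> CVReport:
    """Stratified pair-level k-fold cross-validation of the full pipeline.

    With ``permute_labels`` the label vector is randomly permuted before
    folding, giving the permutation null (out-of-fold AUC near 0.5).
    """
    positives = assoc.pairs()
    negatives = sample_negatives(assoc, seed=cfg.seed)
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    if permute_labels:
        labels = np.random.default_rng(cfg.seed + 7).permutation(labels)

    sim1, sim2 = _semantic_matrices(dag_forest, cfg.semantic)
    coverage = dag_forest_coverage(dag_forest)
    fseq = descriptor_table(records, cfg.kmer_k, cfg.svd_rank)

    if not cfg.mask_held_out:
        sd, sm = _fold_similarities(assoc, sim1, sim2, coverage, fs, cfg)

    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    per_fold: list[FoldMetrics] = []
    rocs: list[tuple[np.ndarray, np.ndarray]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(pairs, labels)):
        y_train, y_test = labels[train_idx], labels[test_idx]
        if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
            raise ValueError(f"fold {fold} lacks one of the two classes")
        train_pairs = [pairs[i] for i in train_idx]
        test_pairs = [pairs[i] for i in test_idx]
        if cfg.mask_held_out:
            # zero the held-out known associations before building profiles
            held_out = [
                p for i, p in zip(test_idx, test_pairs) if i < len(positives)
            ]
            assoc_train = assoc.mask_pairs(held_out)
            sd, sm = _fold_similarities(assoc_train, sim1, sim2, coverage, fs, cfg)
        encoders = fit_block_encoders(
            train_pairs, sd, sm, fseq, cfg.hidden_dims, cfg.ae
        )
        X_train = assemble_table(train_pairs, y_train, sd, sm, fseq, encoders)
        X_test = assemble_table(test_pairs, y_test, sd, sm, fseq, encoders)
        feat_cols = [c for c in X_train.columns if c.startswith("f")]
        clf = train_rf(
            X_train[feat_cols].to_numpy(), y_train, cfg.n_trees, cfg.seed
        )
        scores = clf.predict_proba(X_test[feat_cols].to_numpy())[:, 1]
        metrics, roc = compute_metrics(y_test, scores, cfg.threshold)
        per_fold.append(metrics)
        rocs.append(roc)
    return CVReport(per_fold, rocs)


@dataclass
class FittedModel:
    """Everything needed to score new disease-miRNA pairs."""

    classifier: RandomForestClassifier
    sd: SimilarityMatrix
    sm: SimilarityMatrix
    fseq: pd.DataFrame
    encoders: BlockEncoders
    known_pairs: set[tuple[str, str]]
    mirna_ids: list[str]


def fit_full_model(
    assoc: AssociationMatrix,
    dag_forest: Mapping[str, DiseaseDAG],
    records: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    fs: Optional[SimilarityMatrix] = None,
    cfg: EvalConfig = EvalConfig(),
) -> FittedModel:
    """Train on all known associations (for candidate ranking)."""
    positives = assoc.pairs()
    negatives = sample_negatives(assoc, seed=cfg.seed)
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    sim1, sim2 = _semantic_matrices(dag_forest, cfg.semantic)
    coverage = dag_forest_coverage(dag_forest)
    fseq = descriptor_table(records, cfg.kmer_k, cfg.svd_rank)
    sd, sm = _fold_similarities(assoc, sim1, sim2, coverage, fs, cfg)
    encoders = fit_block_encoders(pairs, sd, sm, fseq, cfg.hidden_dims, cfg.ae)
    table = assemble_table(pairs, labels, sd, sm, fseq, encoders)
    feat_cols = [c for c in table.columns if c.startswith("f")]
    clf = train_rf(table[feat_cols].to_numpy(), labels, cfg.n_trees, cfg.seed)
    return FittedModel(
        clf, sd, sm, fseq, encoders, set(positives), list(assoc.mirna_ids)
    )


def rank_candidates(model: FittedModel, disease_id: str) -> PredictionList:
    """Score every miRNA not already associated with the disease.

    Candidates are sorted by descending score; ties break by identifier
    (lexicographic), so rankings are fully deterministic.
    """
    if disease_id not in model.sd:
        raise KeyError(f"unknown disease {disease_id!r}")
    candidates = [
        m for m in model.mirna_ids if (disease_id, m) not in model.known_pairs
    ]
    if not candidates:
        return PredictionList(disease_id, [])
    table = assemble_table(
        [(disease_id, m) for m in candidates],
        [0] * len(candidates),
        model.sd,
        model.sm,
        model.fseq,
        model.encoders,
    )
    feat_cols = [c for c in table.columns if c.startswith("f")]
    scores = model.classifier.predict_proba(table[feat_cols].to_numpy())[:, 1]
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return PredictionList(disease_id, [(m, float(s)) for m, s in ranked])
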