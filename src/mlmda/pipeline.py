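"""End-to-end orchestration driven by a single TOML config.

``run_pipeline`` executes the stages in order — read inputs, semantic and
GIP similarities, sequence descriptors, cross-validated evaluation, and
optional candidate ranking — persisting each intermediate matrix and a
run manifest (config hash, seeds, package version) so any stage can be
re-run from its inputs and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .autoencoder import AETrainConfig
from .containers import dag_forest_coverage
from .evaluate import (
    CVReport,
    EvalConfig,
    PredictionList,
    crossvalidate,
    fit_full_model,
    rank_candidates,
)
from .gip import GipParams, gip_matrix
from .integrate import integrate_disease, integrate_mirna
from .io import (
    match_sequences,
    read_associations,
    read_dag_forest,
    read_fasta,
    read_similarity_csv,
    write_similarity_csv,
)
from .semantics import SemanticParams, semantic_matrix
from .seqfeat import descriptor_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus every tunable surfaced from the stage modules."""

    associations: Path
    dag_edges: Path
    sequences: Path
    functional_similarity: Optional[Path] = None
    outdir: Path = Path("mlmda_out")
    delta: float = 0.5
    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0
    kmer_k: int = 3
    svd_rank: int = 5
    hidden_dims: tuple[int, int, int] = (16, 16, 32)
    ae_epochs: int = 200
    ae_learning_rate: float = 1.0
    n_trees: int = 100
    threshold: float = 0.5
    folds: int = 5
    seed: int = 42
    predict_diseases: tuple[str, ...] = ()
    top_n: int = 40

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            folds=self.folds,
            n_trees=self.n_trees,
            threshold=self.threshold,
            semantic=SemanticParams(delta=self.delta),
            gip_diseases=GipParams(self.gamma_prime_d),
            gip_mirnas=GipParams(self.gamma_prime_m),
            kmer_k=self.kmer_k,
            svd_rank=self.svd_rank,
            hidden_dims=self.hidden_dims,
            ae=AETrainConfig(
                epochs=self.ae_epochs,
                learning_rate=self.ae_learning_rate,
                seed=self.seed,
            ),
            seed=self.seed,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate the TOML pipeline configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    inputs = raw.get("inputs", {})
    params = raw.get("params", {})
    ae = raw.get("autoencoder", {})
    predict = raw.get("predict", {})
    base = Path(path).parent
    fs = inputs.get("functional_similarity")
    cfg = PipelineConfig(
        associations=base / inputs["associations"],
        dag_edges=base / inputs["dag_edges"],
        sequences=base / inputs["sequences"],
        functional_similarity=(base / fs) if fs else None,
        outdir=base / raw.get("outdir", "mlmda_out"),
        delta=params.get("delta", 0.5),
        gamma_prime_d=params.get("gamma_prime_d", 1.0),
        gamma_prime_m=params.get("gamma_prime_m", 1.0),
        kmer_k=params.get("kmer_k", 3),
        svd_rank=params.get("svd_rank", 5),
        hidden_dims=tuple(ae.get("hidden_dims", (16, 16, 32))),
        ae_epochs=ae.get("epochs", 200),
        ae_learning_rate=ae.get("learning_rate", 1.0),
        n_trees=params.get("n_trees", 100),
        threshold=params.get("threshold", 0.5),
        folds=params.get("folds", 5),
        seed=params.get("seed", 42),
        predict_diseases=tuple(predict.get("diseases", ())),
        top_n=predict.get("top_n", 40),
    )
    if cfg.folds < 2:
        raise ValueError("folds must be >= 2")
    for p in (cfg.associations, cfg.dag_edges, cfg.sequences):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in cfg.__dict__.items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig,
) -> tuple[CVReport, dict[str, PredictionList]]:
    """Run every stage in order, persisting intermediates under outdir."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ecfg = cfg.eval_config()

    logger.info("stage 1: reading inputs")
    try:
        assoc = read_associations(cfg.associations)
        dag_forest = read_dag_forest(cfg.dag_edges)
        records = read_fasta(cfg.sequences)
        fs = (
            read_similarity_csv(cfg.functional_similarity, kind="FS")
            if cfg.functional_similarity
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    assoc, seq_by_id = match_sequences(assoc, records)

    logger.info("stage 2: similarity matrices")
    dag_forest = {d: g for d, g in dag_forest.items() if d in set(assoc.disease_ids)}
    sim1 = semantic_matrix(dag_forest, ecfg.semantic, model=1)
    sim2 = semantic_matrix(dag_forest, ecfg.semantic, model=2)
    kd = gip_matrix(assoc, "diseases", ecfg.gip_diseases)
    km = gip_matrix(assoc, "mirnas", ecfg.gip_mirnas)
    sd = integrate_disease(sim1, sim2, kd, dag_forest_coverage(dag_forest))
    sm = integrate_mirna(fs, km)
    for name, mat in (("sim1", sim1), ("sim2", sim2), ("kd", kd), ("km", km),
                      ("sd", sd), ("sm", sm)):
        write_similarity_csv(mat, out / f"{name}.csv")

    logger.info("stage 3: sequence descriptors")
    fseq = descriptor_table(list(seq_by_id.values()), cfg.kmer_k, cfg.svd_rank)
    fseq.to_csv(out / "fseq.csv", float_format="%.6g")

    logger.info("stage 4: cross-validated evaluation")
    report = crossvalidate(assoc, dag_forest, list(seq_by_id.values()), fs, ecfg)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)
    roc_rows = []
    for fold, (fpr, tpr) in enumerate(report.roc_points):
        roc_rows.append(
            pd.DataFrame({"fold": fold, "fpr": fpr, "tpr": tpr})
        )
    pd.concat(roc_rows).to_csv(out / "roc.csv", index=False)

    predictions: dict[str, PredictionList] = {}
    if cfg.predict_diseases:
        logger.info("stage 5: candidate ranking")
        model = fit_full_model(assoc, dag_forest, list(seq_by_id.values()), fs, ecfg)
        for disease in cfg.predict_diseases:
            plist = rank_candidates(model, disease)
            predictions[disease] = plist
            frame = pd.DataFrame(plist.top(cfg.top_n), columns=["mirna_id", "score"])
            frame.to_csv(out / f"predictions_{disease}.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_diseases": assoc.nd,
        "n_mirnas": assoc.nm,
        "n_positives": int(assoc.values.sum()),
        "mean_cv_auc": report.mean("auc"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report, predictions
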