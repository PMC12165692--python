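"""The two documented end-to-end workflows.

``run_cluster_workflow``: preprocess source and target, build corpora,
pretrain on the source, fine-tune on the target, infer target embeddings,
Leiden-cluster, project to 2-D, score against truth labels when given.
When no source is supplied the model is trained directly on the target
corpus (direct-training mode, also the baseline arm of transfer-learning
comparisons).

``run_algebra_workflow``: balance phenotype classes, build pseudo-bulk
vectors, embed them jointly with the bulk survival cohort, form removal
queries E(T) - E(P), bootstrap the random survival forest, and write the
aggressiveness ranking.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import algebra as alg
from .cluster import clustering_metrics, leiden_cluster, umap_project
from .config import RunConfig, attach_logfile, write_run_metadata
from .corpus import build_documents
from .embed import (EmbeddingMatrix, cosine_similarity, finetune, infer_vectors,
                    load_model, pretrain, save_model)
from .matrix import ExpressionMatrix, read_dense, read_labels, read_mtx
from .preprocess import preprocess_chain

logger = logging.getLogger(__name__)


def _load_matrix(path: str, unit: str) -> ExpressionMatrix:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input not found: {path}")
    if p.is_dir():
        def pick(stem: str) -> Path:
            for suffix in ("", ".gz"):
                for cand in (p / f"{stem}{suffix}",):
                    if cand.exists():
                        return cand
            raise FileNotFoundError(f"{stem}[.gz] not found in {p}")
        return read_mtx(pick("matrix.mtx"), pick("features.tsv"), pick("barcodes.tsv"), unit=unit)
    return read_dense(p, unit=unit)


def run_cluster_workflow(
    config: RunConfig,
    source: ExpressionMatrix | None = None,
    target: ExpressionMatrix | None = None,
    truth: pd.Series | None = None,
    write: bool = True,
):
    """Execute preprocess -> corpus -> (pretrain [-> finetune]) -> infer ->
    cluster -> metrics; returns a dict of all intermediate artifacts."""
    handler = attach_logfile(config.outdir) if write else None
    try:
        if target is None:
            if config.target_path is None:
                raise ValueError("cluster workflow: no target matrix given")
            target = _load_matrix(config.target_path, config.unit)
        if source is None and config.source_path is not None:
            source = _load_matrix(config.source_path, config.unit)
        if truth is None and config.labels_path is not None:
            truth = read_labels(config.labels_path)

        logger.info("target: %d genes x %d cells", target.n_genes, target.n_cells)
        trg_scaled = preprocess_chain(
            target, config.min_genes_per_cell, config.min_cells_per_gene, config.n_top_hvg
        )
        trg_corpus = build_documents(trg_scaled, seed=config.seed_for("corpus-target"))

        if source is not None:
            src_scaled = preprocess_chain(
                source, config.min_genes_per_cell, config.min_cells_per_gene, config.n_top_hvg
            )
            src_corpus = build_documents(src_scaled, seed=config.seed_for("corpus-source"))
            model = pretrain(
                src_corpus, dim=config.dim, window=config.window,
                initial_lr=config.initial_lr, epochs=config.epochs_pretrain,
                seed=config.seed_for("pretrain"), min_count=config.min_count,
            )
            model = finetune(model, trg_corpus, epochs=config.epochs_finetune,
                             seed=config.seed_for("finetune"))
        else:
            logger.info("no source data: training directly on the target corpus")
            model = pretrain(
                trg_corpus, dim=config.dim, window=config.window,
                initial_lr=config.initial_lr, epochs=config.epochs_pretrain,
                seed=config.seed_for("pretrain"), min_count=config.min_count,
            )
        embeddings = infer_vectors(model, trg_corpus, infer_epochs=config.infer_epochs,
                                   seed=config.seed_for("infer"))
        assignment = leiden_cluster(
            embeddings, resolution=config.leiden_resolution,
            n_neighbors=config.n_neighbors, seed=config.seed_for("leiden"),
        )
        coords = umap_project(embeddings, seed=config.seed_for("umap"),
                              n_neighbors=config.n_neighbors)
        metrics = None
        if truth is not None:
            truth = truth.loc[embeddings.ids]
            metrics = clustering_metrics(assignment, truth, embeddings)
            logger.info("metrics: %s", metrics)

        if write:
            out = Path(config.outdir)
            out.mkdir(parents=True, exist_ok=True)
            emb_df = pd.DataFrame(embeddings.vectors, index=embeddings.ids)
            emb_df.index.name = "cell_id"
            emb_df.to_csv(out / "embeddings.csv", float_format="%.8g")
            assignment.to_frame().to_csv(out / "labels.csv", index=False)
            coords.to_csv(out / "umap.csv", index=False, float_format="%.8g")
            if metrics is not None:
                pd.DataFrame([metrics]).to_csv(out / "metrics.tsv", sep="\t", index=False)
            save_model(model, out / "model")
            write_run_metadata(config, out, ["corpus-source", "corpus-target", "pretrain",
                                            "finetune", "infer", "leiden", "umap"])
        return {
            "model": model, "embeddings": embeddings, "clusters": assignment,
            "umap": coords, "metrics": metrics, "scaled": trg_scaled,
        }
    finally:
        if handler is not None:
            logging.getLogger("cellvec").removeHandler(handler)
            handler.close()


def run_algebra_workflow(
    config: RunConfig,
    target: ExpressionMatrix | None = None,
    labels: pd.Series | None = None,
    cohort: alg.SurvivalCohort | None = None,
    model=None,
    write: bool = True,
):
    """Execute balance -> pseudo-bulk -> joint embed -> delta -> bootstrap
    RSF -> rank report; returns the RiskReport and intermediates.

    ``labels`` may be curated phenotype annotations or the cluster
    assignment written by the cluster workflow (algebra on discovered
    clusters).  Without a ``model`` (or ``model_path``) a PV-DM model is
    trained directly on the preprocessed target corpus.
    """
    handler = attach_logfile(config.outdir) if write else None
    try:
        from .preprocess import (filter_cells_genes, minmax_scale_int, normalize_cpm_log,
                                 select_hvg, zscore_scale)

        if target is None:
            if config.target_path is None:
                raise ValueError("algebra workflow: no target matrix given")
            target = _load_matrix(config.target_path, config.unit)
        if labels is None:
            if config.labels_path is None:
                raise ValueError("algebra workflow: no cell-group labels given")
            labels = read_labels(config.labels_path)
        if cohort is None:
            if config.survival_expr_path is None or config.survival_table_path is None:
                raise ValueError("algebra workflow: no survival cohort given")
            expr = read_dense(config.survival_expr_path, unit="bulk_counts")
            table = pd.read_csv(config.survival_table_path)
            cohort = alg.SurvivalCohort.from_table(expr, table)

        filtered = filter_cells_genes(target, config.min_genes_per_cell,
                                      config.min_cells_per_gene)
        normalized = normalize_cpm_log(filtered)
        hvg = select_hvg(normalized, min(config.n_top_hvg, normalized.n_genes))
        normalized_hvg = normalized.subset_genes(hvg)
        labels = pd.Series(labels).astype(str)
        labels = labels.loc[[c for c in normalized_hvg.cell_ids]]

        if model is None:
            if config.model_path is not None:
                model = load_model(config.model_path)
            else:
                logger.info("no model given: training on the target corpus")
                scaled = minmax_scale_int(zscore_scale(normalized, hvg))
                corpus = build_documents(scaled, seed=config.seed_for("corpus-target"))
                model = pretrain(
                    corpus, dim=config.dim, window=config.window,
                    initial_lr=config.initial_lr, epochs=config.epochs_pretrain,
                    seed=config.seed_for("pretrain"), min_count=config.min_count,
                )

        balanced, bal_labels = alg.balance_classes(
            normalized_hvg, labels, seed=config.seed_for("balance"),
            k_neighbors=config.smote_k,
        )
        queries = config.algebra_queries or [f"T - {g}" for g in sorted(bal_labels.unique())]
        pseudobulks = alg.make_pseudobulk(balanced, bal_labels, queries)
        emb, roles = alg.joint_embed(
            cohort, pseudobulks, model, seed=config.seed_for("joint-embed"),
            infer_epochs=config.infer_epochs, min_common_genes=config.min_common_genes,
        )
        bulk_ids = [i for i in emb.ids if roles[i] == "bulk"]
        bulk_emb = emb.subset(bulk_ids)
        ref_vec = emb.row(alg.REFERENCE_NAME)
        query_names = [pb.name for pb in pseudobulks if pb.role != "reference"]
        deltas = np.vstack([alg.delta_embedding(ref_vec, emb.row(q)) for q in query_names])
        cos = {q: cosine_similarity(ref_vec, emb.row(q)) for q in query_names}
        delta_emb = EmbeddingMatrix(ids=query_names, vectors=deltas)
        report = alg.bootstrap_risk(
            delta_emb, bulk_emb, cohort,
            n_boot=config.n_boot, train_frac=config.train_frac,
            seed=config.seed_for("bootstrap"), n_estimators=config.n_estimators,
            min_samples_leaf=config.rsf_min_samples_leaf, cosine_to_reference=cos,
        )
        table = alg.rank_report(report, outdir=config.outdir if write else None)
        if write:
            import json

            out = Path(config.outdir)
            payload = report.to_dict()
            payload["config_hash"] = config.content_hash()
            (out / "risk_report.json").write_text(json.dumps(payload, sort_keys=True))
            write_run_metadata(config, out, ["corpus-target", "pretrain", "balance",
                                            "joint-embed", "bootstrap"])
        logger.info("aggressiveness ranking: %s", report.ranking)
        return {"report": report, "table": table, "embeddings": emb, "roles": roles,
                "pseudobulks": pseudobulks, "model": model}
    finally:
        if handler is not None:
            logging.getLogger("cellvec").removeHandler(handler)
            handler.close()
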