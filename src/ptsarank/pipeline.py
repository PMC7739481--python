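"""End-to-end orchestration: similarity → graph → GCN → boosting → evaluation.

`run_pipeline` consumes a configuration mapping (paths of the four input
files plus stage settings), executes the stages in order, writes every
intermediate artifact to the output directory, and logs seeds, package
version and input checksums for auditability.  It can stop after any named
stage.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import __version__, io
from .boosting import BoostingConfig
from .disease_graph import build_disease_graph, encode_protein_features, select_frequent_proteins
from .evaluation import PipelineConfig, rank_candidates, run_loocv
from .gcn import GcnConfig, embed_nodes, train_gcn
from .similarity import similarity_matrix

STAGES = ("similarity", "graph", "gcn", "evaluate", "rank")

logger = logging.getLogger("ptsarank")


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    fileh = logging.FileHandler(outdir / "pipeline.log")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, fileh):
        h.setFormatter(fmt)
        logger.addHandler(h)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def pipeline_config_from_dict(cfg: Dict) -> PipelineConfig:
    gcn = GcnConfig(**cfg.get("gcn", {}))
    boosting = BoostingConfig(**cfg.get("boosting", {}))
    return PipelineConfig(
        gcn=gcn,
        boosting=boosting,
        feature_mode=cfg.get("feature_mode", "embedding"),
        reuse_global_embedding=cfg.get("reuse_global_embedding", False),
    )


def run_pipeline(cfg: Dict, stop_after: Optional[str] = None) -> Dict:
    """Run the pipeline described by ``cfg``; return the report mapping.

    Required keys: ``gene_network``, ``disease_genes``, ``disease_proteins``,
    ``labels`` (input paths) and ``outdir``.  Optional: ``similarity_mode``,
    ``edge_threshold``, ``min_diseases``, ``evaluation_seed``, ``rank`` (with
    ``n_negatives``/``seed``/``threshold``), and the nested ``gcn``,
    ``boosting``, ``feature_mode`` settings.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; expected one of {STAGES}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("ptsarank %s", __version__)

    inputs = {k: cfg[k] for k in ("gene_network", "disease_genes", "disease_proteins", "labels")}
    for name, path in inputs.items():
        logger.info("input %s = %s (sha256:%s)", name, path, _checksum(path))

    def _stage_guard(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # similarity
    def _similarity():
        network = io.read_edge_list(inputs["gene_network"])
        gene_map = io.read_disease_gene_map(inputs["disease_genes"])
        mode = cfg.get("similarity_mode", "corrected")
        sim, ids = similarity_matrix(gene_map, network, mode=mode)
        io.write_matrix(sim, ids, outdir / "similarity.tsv")
        logger.info("similarity matrix: %d diseases (mode=%s)", len(ids), mode)
        return sim, ids

    sim, ids = _stage_guard("similarity", _similarity)
    report: Dict = {"version": __version__, "n_diseases": len(ids)}
    if stop_after == "similarity":
        return report

    # graph assembly
    def _graph():
        protein_map = io.read_disease_protein_map(inputs["disease_proteins"])
        positives = set(io.read_labels(inputs["labels"]))
        selected = select_frequent_proteins(protein_map, cfg.get("min_diseases", 100))
        X = encode_protein_features(protein_map, selected, disease_ids=ids)
        y = [int(d in positives) for d in ids]
        graph = build_disease_graph(
            sim, X, y, ids, edge_threshold=cfg.get("edge_threshold", 0.0)
        )
        io.write_graph_bundle(graph, selected, outdir)
        logger.info("disease graph: %d nodes, %d features", graph.n_nodes, len(selected))
        return graph

    graph = _stage_guard("graph", _graph)
    report["n_features"] = graph.features.shape[1]
    if stop_after == "graph":
        return report

    pipe = pipeline_config_from_dict(cfg)

    # one GCN fit on the full labeled graph for the exported embedding artifact
    def _gcn():
        model = train_gcn(graph, pipe.gcn)
        emb = embed_nodes(graph, model)
        io.write_embeddings(emb, graph.node_ids, outdir / "embeddings.tsv")
        logger.info("gcn: hidden_dim=%d final_loss=%.6f", pipe.gcn.hidden_dim, model.loss_trace[-1])
        return emb

    if pipe.feature_mode != "raw":
        _stage_guard("gcn", _gcn)
    if stop_after == "gcn":
        return report

    # evaluation (per-fold refits; the exported embedding above is audit-only)
    def _evaluate():
        seed = cfg.get("evaluation_seed", 0)
        rep = run_loocv(graph, pipe, seed=seed)
        io.write_scores(rep.scores_frame(), outdir / "loocv_scores.tsv")
        io.write_report(rep.to_dict(), outdir / "report.json")
        logger.info("loocv: roc_auc=%.4f pr_auc=%.4f", rep.roc_auc, rep.pr_auc)
        return rep

    rep = _stage_guard("evaluate", _evaluate)
    report.update(roc_auc=rep.roc_auc, pr_auc=rep.pr_auc)
    if stop_after == "evaluate":
        return report

    # candidate ranking
    def _rank():
        rank_cfg = cfg.get("rank", {})
        table = rank_candidates(
            graph,
            pipe,
            n_negatives=rank_cfg.get("n_negatives", 100),
            seed=rank_cfg.get("seed", 0),
            threshold=rank_cfg.get("threshold", 0.5),
        )
        io.write_scores(table, outdir / "candidate_ranking.tsv")
        logger.info("rank: %d candidates, %d above threshold", len(table), int(table.predicted.sum()))
        return table

    table = _stage_guard("rank", _rank)
    report["n_predicted"] = int(table.predicted.sum())
    return report
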