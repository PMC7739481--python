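"""Leave-one-positive-out evaluation, ranking metrics, and candidate ranking.

With only a handful of known positives, the evaluation scheme builds one
fold per known positive: the unknown diseases are shuffled into as many
near-equal groups as there are positives, and fold *t* holds out positive
*t* together with group *t* as its test negatives.  Within each fold the
encoder and the classifier are refit on the training nodes only (test
labels masked during GCN training), held-out scores are pooled across
folds, and ROC-AUC / PR-AUC are computed once on the pooled scores.

PR-AUC uses the average-precision (step) convention — no linear
interpolation between operating points — because interpolated AUPR is
optimistic on skewed label sets like this one.

The candidate-ranking mode mirrors the discovery use of the tool: train on
all known positives plus a random sample of unknowns relabeled as
negatives, then score every unlabeled disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .boosting import BoostingConfig, fit as fit_boosting, predict_proba
from .disease_graph import DiseaseGraph, UNLABELED
from .gcn import GcnConfig, embed_nodes, train_gcn

FEATURE_MODES = ("embedding", "raw", "concat")


@dataclass
class PipelineConfig:
    """Encoder + classifier settings for one evaluation run.

    ``feature_mode`` selects what the booster sees: GCN hidden activations
    (``"embedding"``, the default), the raw binary protein features
    (``"raw"``, the encoder-free baseline), or both concatenated
    (``"concat"``).  ``reuse_global_embedding`` trains the GCN once on the
    full labeled graph and reuses that embedding in every fold — fast but
    LEAKY (test labels influence the embedding); it exists for exploratory
    runs only and is never the default.
    """

    gcn: GcnConfig = field(default_factory=GcnConfig)
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    feature_mode: str = "embedding"
    reuse_global_embedding: bool = False

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")


@dataclass(frozen=True)
class FoldPlan:
    """One fold per positive: (test positive index, test unknown-group indices)."""

    folds: Tuple[Tuple[int, Tuple[int, ...]], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def test_indices(self, fold: int) -> List[int]:
        pos, group = self.folds[fold]
        return [pos, *group]


def make_loocv_folds(labels: Sequence[int], seed: int) -> FoldPlan:
    """Partition diseases into one fold per known positive.

    Unknowns are shuffled by ``seed`` and split into ``n_positives``
    near-equal groups (sizes differ by at most 1); every disease appears in
    exactly one test fold.
    """
    y = np.asarray(labels, dtype=int)
    pos_idx = np.flatnonzero(y == 1)
    unk_idx = np.flatnonzero(y == 0)
    if len(pos_idx) < 2:
        raise ValueError("need at least 2 positives to build folds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unk_idx)
    groups = np.array_split(shuffled, len(pos_idx))
    folds = tuple(
        (int(p), tuple(int(i) for i in grp)) for p, grp in zip(pos_idx, groups)
    )
    return FoldPlan(folds=folds, seed=seed)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2).

    Computed by the rank-sum identity with midranks, which is exactly the
    tie-aware pair-counting definition.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve (average precision).

    AP = sum_k (R_k - R_{k-1}) * P_k over descending score thresholds, with
    tied scores entering at the same threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("PR-AUC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # last index of each tied block = an operating point
    block_end = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp = np.cumsum(y == 1)[block_end]
    n_seen = block_end + 1
    precision = tp / n_seen
    recall = tp / n_pos
    delta_r = np.diff(np.r_[0.0, recall])
    return float((delta_r * precision).sum())


@dataclass
class EvalReport:
    """Pooled held-out scores and ranking metrics of one evaluation run."""

    node_ids: Tuple[str, ...]
    scores: np.ndarray
    fold_plan: FoldPlan
    roc_auc: float
    pr_auc: float
    seed: int
    config: Dict

    def to_dict(self) -> Dict:
        return {
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "seed": self.seed,
            "n_folds": self.fold_plan.n_folds,
            "config": self.config,
        }

    def scores_frame(self) -> pd.DataFrame:
        fold_of = np.empty(len(self.node_ids), dtype=int)
        for t in range(self.fold_plan.n_folds):
            fold_of[self.fold_plan.test_indices(t)] = t
        return pd.DataFrame(
            {"disease": self.node_ids, "score": self.scores, "fold": fold_of}
        )


def _fold_features(graph: DiseaseGraph, masked: DiseaseGraph, config: PipelineConfig) -> np.ndarray:
    if config.feature_mode == "raw":
        return graph.features
    model = train_gcn(masked, config.gcn)
    emb = embed_nodes(masked, model)
    if config.feature_mode == "concat":
        return np.hstack([graph.features, emb])
    return emb


def _config_echo(config: PipelineConfig) -> Dict:
    return {
        "feature_mode": config.feature_mode,
        "reuse_global_embedding": config.reuse_global_embedding,
        "gcn": vars(config.gcn).copy(),
        "boosting": vars(config.boosting).copy(),
    }


def run_loocv(graph: DiseaseGraph, config: PipelineConfig, seed: int = 0) -> EvalReport:
    """Leave-one-positive-out evaluation of the full pipeline.

    Per fold: mask the test nodes' labels, refit the GCN on the masked graph
    (unless ``feature_mode="raw"``), fit the booster on the training nodes,
    and score the test nodes.  Metrics are computed on the pooled held-out
    scores only.
    """
    y = graph.labels
    if UNLABELED in y:
        raise ValueError("evaluation graph must be fully labeled (0/1)")
    plan = make_loocv_folds(y, seed)
    scores = np.full(graph.n_nodes, np.nan)

    global_features = None
    if config.reuse_global_embedding and config.feature_mode != "raw":
        model = train_gcn(graph, config.gcn)
        emb = embed_nodes(graph, model)
        global_features = (
            np.hstack([graph.features, emb]) if config.feature_mode == "concat" else emb
        )

    for t in range(plan.n_folds):
        test_idx = np.array(plan.test_indices(t))
        masked = graph.masked(test_idx)
        F = global_features if global_features is not None else _fold_features(
            graph, masked, config
        )
        train_mask = np.ones(graph.n_nodes, dtype=bool)
        train_mask[test_idx] = False
        booster = fit_boosting(F[train_mask], y[train_mask], config.boosting)
        scores[test_idx] = predict_proba(booster, F[test_idx])

    return EvalReport(
        node_ids=graph.node_ids,
        scores=scores,
        fold_plan=plan,
        roc_auc=roc_auc(scores, y),
        pr_auc=pr_auc(scores, y),
        seed=seed,
        config=_config_echo(config),
    )


def rank_candidates(
    graph: DiseaseGraph,
    config: PipelineConfig,
    n_negatives: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every unlabeled disease after training on positives + sampled negatives.

    ``n_negatives`` unknowns are sampled (by ``seed``) and treated as the
    negative class; the model then scores all unknown diseases.  Returns a
    descending-score table with a boolean ``predicted`` column at the given
    decision threshold.
    """
    y = graph.labels
    unk_idx = np.flatnonzero(y == 0)
    if len(unk_idx) < n_negatives:
        raise ValueError(
            f"need at least {n_negatives} unknown diseases, have {len(unk_idx)}"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(unk_idx, size=n_negatives, replace=False)

    train_labels = np.full(graph.n_nodes, UNLABELED)
    train_labels[y == 1] = 1
    train_labels[neg_idx] = 0
    train_graph = DiseaseGraph(graph.node_ids, graph.adjacency, graph.features, train_labels)

    if config.feature_mode == "raw":
        F = graph.features
    else:
        model = train_gcn(train_graph, config.gcn)
        emb = embed_nodes(train_graph, model)
        F = np.hstack([graph.features, emb]) if config.feature_mode == "concat" else emb

    train_mask = train_labels != UNLABELED
    booster = fit_boosting(F[train_mask], train_labels[train_mask], config.boosting)
    candidate_scores = predict_proba(booster, F[unk_idx])

    table = pd.DataFrame(
        {
            "disease": [graph.node_ids[i] for i in unk_idx],
            "score": candidate_scores,
            "predicted": candidate_scores >= threshold,
        }
    )
    return table.sort_values(
        ["score", "disease"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
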