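"""Second-order gradient-boosted CART trees, written from scratch.

Each boosting round fits one regression tree to the per-sample gradient g
and hessian h of the binary logistic loss evaluated at the current margin.
Splits are found by exact greedy search: every feature, every midpoint
between consecutive distinct sorted values, scored by the regularized gain

    Gain = 1/2 * (G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                  - (G_L+G_R)^2/(H_L+H_R+lambda)) - gamma

with leaf weights w* = -G/(H+lambda).  gamma penalizes each additional
leaf, lambda shrinks leaf weights.  Ties in gain resolve to the lowest
feature index, then the lowest threshold, so fits are fully deterministic.

The classical gradient-boosting initialization and leaf-value formulas for
{-1, +1} labels (half-log-odds start, per-leaf Newton-style ratio of
pseudo-residuals) are provided as standalone reference operations.

No column/row subsampling, no histogram approximation, no sparse-aware
default directions: absent features are literal zeros in the binary
protein encoding, so dense and sparse views of the same matrix predict
identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def logistic_gradients(margin, label) -> Tuple[np.ndarray, np.ndarray]:
    """Gradient and hessian of the logistic loss at the given margin.

    For p = sigmoid(margin): g = p - y, h = p (1 - p).  Accepts scalars or
    arrays.
    """
    p = sigmoid(np.asarray(margin, dtype=float))
    y = np.asarray(label, dtype=float)
    return p - y, p * (1.0 - p)


def leaf_weight(G: float, H: float, lam: float) -> float:
    """Optimal leaf value -G / (H + lambda)."""
    if H + lam <= 0:
        raise ValueError(f"H + lambda must be positive, got {H + lam}")
    return -G / (H + lam)


def structure_score(leaf_stats: Sequence[Tuple[float, float]], lam: float, gamma: float) -> float:
    """Objective of a fixed tree structure: -1/2 sum G_j^2/(H_j+lambda) + gamma * T."""
    total = 0.0
    for G, H in leaf_stats:
        if H + lam <= 0:
            raise ValueError(f"H + lambda must be positive, got {H + lam}")
        total += G * G / (H + lam)
    return -0.5 * total + gamma * len(leaf_stats)


def split_gain(GL: float, HL: float, GR: float, HR: float, lam: float, gamma: float) -> float:
    """Objective reduction from one split, minus the leaf penalty gamma."""
    for H in (HL, HR):
        if H + lam <= 0:
            raise ValueError(f"child H + lambda must be positive, got {H + lam}")
    G = GL + GR
    return 0.5 * (GL * GL / (HL + lam) + GR * GR / (HR + lam) - G * G / (HL + HR + lam)) - gamma


@dataclass
class BoostingConfig:
    n_rounds: int = 50
    max_depth: int = 3
    learning_rate: float = 0.1
    lam: float = 1.0
    gamma: float = 0.0
    min_child_hessian: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.max_depth < 0:
            raise ValueError("n_rounds must be >= 1 and max_depth >= 0")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.lam < 0 or self.gamma < 0 or self.min_child_hessian < 0:
            raise ValueError("lam, gamma and min_child_hessian must be >= 0")


@dataclass
class TreeNode:
    """CART node: either an internal split or a leaf with a weight.

    node_stats holds the (G, H) gradient/hessian sums of the samples routed
    through the node, kept for structure-score audits.
    """

    split_feature: Optional[int] = None
    split_threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    weight: Optional[float] = None
    node_stats: Tuple[float, float] = (0.0, 0.0)

    @property
    def is_leaf(self) -> bool:
        return self.weight is not None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf values for each row of X (samples go left on value <= threshold)."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        self._predict_into(X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if self.is_leaf:
            out[idx] = self.weight
            return
        go_left = X[idx, self.split_feature] <= self.split_threshold
        self.left._predict_into(X, idx[go_left], out)
        self.right._predict_into(X, idx[~go_left], out)

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> List["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()


def _best_split(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, idx: np.ndarray, config: BoostingConfig
) -> Optional[Tuple[int, float, float]]:
    """Exact greedy search over all features and midpoints.

    Returns (feature, threshold, gain) of the best admissible split, or None.
    Ties resolve to lowest feature index, then lowest threshold.
    """
    G = g[idx].sum()
    H = h[idx].sum()
    best: Optional[Tuple[int, float, float]] = None
    for j in range(X.shape[1]):
        values = X[idx, j]
        order = np.argsort(values, kind="stable")
        v = values[order]
        gs = np.cumsum(g[idx][order])
        hs = np.cumsum(h[idx][order])
        # candidate cut after position k iff v[k] != v[k+1]
        cuts = np.flatnonzero(v[:-1] != v[1:])
        for k in cuts:
            HL = hs[k]
            HR = H - HL
            if HL < config.min_child_hessian or HR < config.min_child_hessian:
                continue
            GL = gs[k]
            gain = split_gain(GL, HL, G - GL, HR, config.lam, config.gamma)
            threshold = 0.5 * (v[k] + v[k + 1])
            if best is None or gain > best[2] + 1e-15:
                best = (j, threshold, gain)
    return best


def build_tree(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, config: BoostingConfig
) -> TreeNode:
    """Grow one regression tree on gradient/hessian targets.

    Stops on max_depth, non-positive best gain, or a child hessian sum below
    min_child_hessian; leaves get the optimal -G/(H+lambda) weight.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need at least one sample with 2-D features")
    if not (np.isfinite(g).all() and np.isfinite(h).all()):
        raise ValueError("gradients and hessians must be finite")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        G = g[idx].sum()
        H = h[idx].sum()
        node = TreeNode(node_stats=(float(G), float(H)))
        found = _best_split(X, g, h, idx, config) if depth < config.max_depth else None
        if found is None or found[2] <= 0:
            node.weight = leaf_weight(G, H, config.lam)
            return node
        j, threshold, _ = found
        node.split_feature = j
        node.split_threshold = threshold
        go_left = X[idx, j] <= threshold
        node.left = grow(idx[go_left], depth + 1)
        node.right = grow(idx[~go_left], depth + 1)
        return node

    return grow(np.arange(X.shape[0]), 0)


@dataclass
class BoostedModel:
    """Additive ensemble: margin(x) = base_score + lr * sum_t tree_t(x)."""

    base_score: float
    trees: List[TreeNode]
    config: BoostingConfig

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        margin = np.full(X.shape[0], self.base_score)
        for tree in self.trees:
            margin += self.config.learning_rate * tree.predict(X)
        return margin


def fit(X: np.ndarray, labels: Sequence[int], config: BoostingConfig) -> BoostedModel:
    """Train the boosted classifier on {0, 1} labels.

    Margins start at 0 (so the first round's leaves are Newton steps at the
    prior p = 0.5) and accumulate learning_rate-scaled tree outputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows and labels disagree")
    if not (0 in y and 1 in y):
        raise ValueError("training requires both classes present")
    margin = np.zeros(X.shape[0])
    trees: List[TreeNode] = []
    for _ in range(config.n_rounds):
        g, h = logistic_gradients(margin, y)
        tree = build_tree(X, g, h, config)
        margin += config.learning_rate * tree.predict(X)
        trees.append(tree)
    return BoostedModel(base_score=0.0, trees=trees, config=config)


def predict_proba(model: BoostedModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities: sigmoid of the accumulated margin."""
    X = np.asarray(X, dtype=float)
    if model.trees and X.ndim != 2:
        raise ValueError("features must be 2-D")
    return sigmoid(model.predict_margin(X))


# ---------------------------------------------------------------------------
# classical GBDT reference operations ({-1, +1} labels)

def gbdt_init_score(labels: Sequence[int]) -> float:
    """Half-log-odds initialization F_0 = 1/2 log((1+ybar)/(1-ybar)) for {-1,1} labels."""
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    ybar = y.mean()
    if not -1.0 < ybar < 1.0:
        raise ValueError("all-identical labels give an infinite initial score")
    return 0.5 * np.log((1.0 + ybar) / (1.0 - ybar))


def gbdt_leaf_value(pseudo_residuals: Sequence[float]) -> float:
    """Per-leaf value sum(r) / sum(|r| (2 - |r|)) of the classical algorithm."""
    r = np.asarray(pseudo_residuals, dtype=float)
    if r.size == 0:
        raise ValueError("leaf region must be non-empty")
    denom = (np.abs(r) * (2.0 - np.abs(r))).sum()
    if denom == 0:
        raise ValueError("degenerate leaf: zero denominator in the leaf-value formula")
    return float(r.sum() / denom)


# ---------------------------------------------------------------------------
# serialization

def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"weight": node.weight, "stats": list(node.node_stats)}
    return {
        "feature": node.split_feature,
        "threshold": node.split_threshold,
        "stats": list(node.node_stats),
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "weight" in d:
        return TreeNode(weight=d["weight"], node_stats=tuple(d["stats"]))
    return TreeNode(
        split_feature=d["feature"],
        split_threshold=d["threshold"],
        node_stats=tuple(d["stats"]),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def model_to_json(model: BoostedModel) -> str:
    """Serialize the ensemble (trees, base score, config) to a JSON string."""
    payload = {
        "base_score": model.base_score,
        "config": {
            "n_rounds": model.config.n_rounds,
            "max_depth": model.config.max_depth,
            "learning_rate": model.config.learning_rate,
            "lam": model.config.lam,
            "gamma": model.config.gamma,
            "min_child_hessian": model.config.min_child_hessian,
            "seed": model.config.seed,
        },
        "trees": [_node_to_dict(t) for t in model.trees],
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> BoostedModel:
    payload = json.loads(text)
    config = BoostingConfig(**payload["config"])
    trees = [_node_from_dict(t) for t in payload["trees"]]
    return BoostedModel(base_score=payload["base_score"], trees=trees, config=config)
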