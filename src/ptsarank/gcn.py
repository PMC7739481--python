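"""Spectral graph operators and the graph convolutional encoder.

The encoder is a standard two-layer GCN.  One layer computes
``H' = sigma(K H W)`` where ``K = D^{-1/2} A D^{-1/2}`` is the symmetric
normalized adjacency (with self-loops added by default, so each node's own
features survive propagation) and ``D`` the corresponding degree matrix.
Degree-0 nodes get zero rows/columns in ``K`` rather than raising — the
standard convention for the normalized Laplacian of graphs with isolated
vertices.

Training is full-batch gradient descent on softmax cross-entropy over the
labeled nodes only; unlabeled (masked) nodes still participate in
propagation but contribute nothing to the objective, which is how held-out
nodes are embedded without label leakage.  The hidden-layer activations are
the per-node embeddings handed to the downstream classifier.

The Chebyshev polynomial basis and the first-order spectral filter are
exposed as standalone operators: with K = 1 and lambda_max = 2 the
Chebyshev expansion collapses to exactly the single-parameter layer above,
which the tests verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .disease_graph import DiseaseGraph, UNLABELED


def degree_matrix(A: np.ndarray) -> np.ndarray:
    """Diagonal matrix of row sums of the (possibly self-looped) adjacency."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if (A < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    return np.diag(A.sum(axis=1))


def laplacian(A: np.ndarray) -> np.ndarray:
    """Combinatorial graph Laplacian D - A; rows sum to zero."""
    return degree_matrix(A) - np.asarray(A, dtype=float)


def sym_normalized_operator(
    A: np.ndarray, self_loops: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Symmetric normalized Laplacian and propagation kernel.

    Returns ``(L_sym, K)`` with ``K = D^{-1/2} Â D^{-1/2}`` and
    ``L_sym = I - K`` off the degree-0 convention, where ``Â = A + I`` when
    ``self_loops`` is set.  Rows/columns of degree-0 nodes are zero in K and
    their L_sym diagonal entry is zero (not one).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    A_hat = A + np.eye(A.shape[0]) if self_loops else A
    deg = A_hat.sum(axis=1)
    nonzero = deg > 0
    inv_sqrt = np.zeros_like(deg)
    inv_sqrt[nonzero] = deg[nonzero] ** -0.5
    K = inv_sqrt[:, None] * A_hat * inv_sqrt[None, :]
    L_sym = np.diag(nonzero.astype(float)) - K
    return L_sym, K


def chebyshev_polynomials(x: float, K: int) -> List[float]:
    """Chebyshev polynomials of the first kind, [T_0(x), ..., T_K(x)].

    T_0 = 1, T_1 = x, T_k = 2 x T_{k-1} - T_{k-2}.
    """
    if K < 0:
        raise ValueError("order K must be >= 0")
    values = [1.0]
    if K >= 1:
        values.append(float(x))
    for _ in range(2, K + 1):
        values.append(2.0 * x * values[-1] - values[-2])
    return values


def first_order_filter(
    x: np.ndarray, A: np.ndarray, theta0: float, theta1: float, self_loops: bool = False
) -> np.ndarray:
    """First-order spectral graph filter theta0 * x - theta1 * K x.

    The first-order truncation of the Chebyshev expansion with lambda_max = 2
    applied to a node signal; K is the symmetric normalized adjacency.
    """
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    if x.shape[0] != A.shape[0]:
        raise ValueError(f"signal length {x.shape[0]} != node count {A.shape[0]}")
    _, kernel = sym_normalized_operator(A, self_loops=self_loops)
    return theta0 * x - theta1 * (kernel @ x)


_ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "identity": lambda z: z,
}


@dataclass
class GcnConfig:
    """Encoder hyperparameters.

    ``hidden_dim`` is the embedding width; ``lr`` is the full-batch gradient
    descent step size, small enough that the loss trace is monotone on the
    bundled scenarios; ``self_loops`` toggles Â = A + I before normalization.
    """

    hidden_dim: int = 64
    epochs: int = 400
    lr: float = 0.2
    self_loops: bool = True
    hidden_activation: str = "relu"
    seed: int = 0


@dataclass
class GcnModel:
    """Trained two-layer GCN: weights, cached propagation kernel, loss trace."""

    layer_weights: List[np.ndarray]
    kernel: np.ndarray
    config: GcnConfig
    loss_trace: List[float] = field(default_factory=list)
    trained: bool = False


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_layer_forward(H: np.ndarray, model: GcnModel, layer_index: int) -> np.ndarray:
    """One propagation step: sigma(K H W) for the given layer.

    The hidden layer uses the configured nonlinearity; the output layer is
    linear (its softmax lives inside the training loss).
    """
    W = model.layer_weights[layer_index]
    H = np.asarray(H, dtype=float)
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"input width {H.shape[1]} != layer in-dim {W.shape[0]}")
    Z = model.kernel @ H @ W
    if layer_index < len(model.layer_weights) - 1:
        return _ACTIVATIONS[model.config.hidden_activation](Z)
    return Z


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def train_gcn(graph: DiseaseGraph, config: GcnConfig) -> GcnModel:
    """Fit the two-layer encoder by full-batch gradient descent.

    Cross-entropy is averaged over labeled nodes only (labels 0/1); masked
    nodes propagate features but are excluded from the loss.  Deterministic
    given the config seed.
    """
    labeled = graph.labels != UNLABELED
    if not labeled.any():
        raise ValueError("cannot train: no labeled nodes")
    y = graph.labels[labeled]
    if not (1 in y and 0 in y):
        raise ValueError("training requires at least one positive and one negative label")

    rng = np.random.default_rng(config.seed)
    X = graph.features
    n_feat = X.shape[1]
    W1 = _glorot(rng, n_feat, config.hidden_dim)
    W2 = _glorot(rng, config.hidden_dim, 2)
    _, K = sym_normalized_operator(graph.adjacency, self_loops=config.self_loops)
    act = _ACTIVATIONS[config.hidden_activation]

    Y = np.zeros((graph.n_nodes, 2))
    Y[labeled, graph.labels[labeled]] = 1.0
    n_labeled = int(labeled.sum())
    KX = K @ X  # constant across epochs

    trace: List[float] = []
    for _ in range(config.epochs):
        Z1 = KX @ W1
        H1 = act(Z1)
        KH1 = K @ H1
        logits = KH1 @ W2
        P = _softmax(logits)
        loss = -np.mean(np.log(P[labeled, graph.labels[labeled]] + 1e-12))
        trace.append(float(loss))

        dlogits = (P - Y) / n_labeled
        dlogits[~labeled] = 0.0
        dW2 = KH1.T @ dlogits
        dH1 = K @ (dlogits @ W2.T)
        if config.hidden_activation == "relu":
            dZ1 = dH1 * (Z1 > 0)
        else:
            dZ1 = dH1
        dW1 = KX.T @ dZ1
        W1 -= config.lr * dW1
        W2 -= config.lr * dW2

    return GcnModel(layer_weights=[W1, W2], kernel=K, config=config, loss_trace=trace, trained=True)


def embed_nodes(graph: DiseaseGraph, model: GcnModel) -> np.ndarray:
    """Hidden-layer activations per node (n_nodes x hidden_dim)."""
    if not model.trained:
        raise ValueError("model must be trained before embedding")
    return gcn_layer_forward(graph.features, model, 0)


def predict_proba_gcn(graph: DiseaseGraph, model: GcnModel) -> np.ndarray:
    """Softmax class probabilities from the full forward pass (n_nodes x 2)."""
    if not model.trained:
        raise ValueError("model must be trained before predicting")
    H1 = gcn_layer_forward(graph.features, model, 0)
    return _softmax(gcn_layer_forward(H1, model, 1))
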