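"""Protein-feature encoding, frequency filtering, and disease-graph assembly.

Each disease is represented by a binary vector over a selected protein
panel (1 iff the protein is annotated to the disease).  Because protein
annotations follow a heavy-tailed frequency distribution, only proteins
associated with at least ``min_diseases`` diseases are kept as features.
The labeled disease graph combines the similarity-derived adjacency with
these node features and partial labels (1 = known positive, 0 = unknown,
-1 = masked/unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Tuple

import numpy as np

UNLABELED = -1


@dataclass(frozen=True)
class DiseaseProteinMap:
    """Mapping from disease IDs to annotated protein sets, with a fixed universe."""

    protein_sets: Mapping[str, FrozenSet[str]]
    universe: Tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "DiseaseProteinMap":
        sets: Dict[str, set] = {}
        universe: set[str] = set()
        for disease, protein in pairs:
            sets.setdefault(disease, set()).add(protein)
            universe.add(protein)
        return cls({d: frozenset(p) for d, p in sets.items()}, tuple(sorted(universe)))

    @property
    def disease_ids(self) -> Tuple[str, ...]:
        return tuple(sorted(self.protein_sets))

    def proteins_of(self, disease: str) -> FrozenSet[str]:
        return self.protein_sets.get(disease, frozenset())

    def pairs(self) -> list[Tuple[str, str]]:
        return sorted((d, p) for d, ps in self.protein_sets.items() for p in ps)


def select_frequent_proteins(dmap: DiseaseProteinMap, min_diseases: int) -> list[str]:
    """Proteins annotated to at least ``min_diseases`` diseases.

    Ordered by descending disease count, identifier ascending on ties, so
    the feature column order is deterministic across runs.
    """
    if min_diseases < 1:
        raise ValueError("min_diseases must be >= 1")
    counts: Dict[str, int] = {p: 0 for p in dmap.universe}
    for proteins in dmap.protein_sets.values():
        for p in proteins:
            counts[p] += 1
    kept = [p for p in dmap.universe if counts[p] >= min_diseases]
    if not kept:
        raise ValueError(
            f"no features survive filter: no protein is associated with "
            f">= {min_diseases} diseases (max observed {max(counts.values(), default=0)})"
        )
    kept.sort(key=lambda p: (-counts[p], p))
    return kept


def encode_protein_features(
    dmap: DiseaseProteinMap,
    selected: Sequence[str],
    disease_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Binary disease-by-protein incidence matrix over the selected panel.

    Row order follows ``disease_ids`` (default: sorted IDs from the map);
    column order follows ``selected``.
    """
    universe = set(dmap.universe)
    unknown = [p for p in selected if p not in universe]
    if unknown:
        raise ValueError(f"selected proteins not in universe: {unknown[:5]}")
    if disease_ids is None:
        disease_ids = dmap.disease_ids
    col = {p: j for j, p in enumerate(selected)}
    X = np.zeros((len(disease_ids), len(selected)))
    for i, d in enumerate(disease_ids):
        for p in dmap.proteins_of(d):
            j = col.get(p)
            if j is not None:
                X[i, j] = 1.0
    return X


@dataclass
class DiseaseGraph:
    """Labeled disease graph: adjacency from similarities, binary node features.

    ``adjacency`` is symmetric, non-negative, zero on the diagonal (self-loops
    are added, when requested, inside the GCN normalization).  ``labels`` take
    values 1 (known positive), 0 (unknown, treated as negative by the
    classifier) or -1 (masked, excluded from any training objective).
    """

    node_ids: Tuple[str, ...]
    adjacency: np.ndarray
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.adjacency.shape != (n, n):
            raise ValueError(f"adjacency shape {self.adjacency.shape} != ({n}, {n})")
        if self.features.shape[0] != n:
            raise ValueError(f"feature rows {self.features.shape[0]} != {n} nodes")
        if self.labels.shape != (n,):
            raise ValueError(f"labels shape {self.labels.shape} != ({n},)")
        if not set(np.unique(self.labels)) <= {UNLABELED, 0, 1}:
            raise ValueError("labels must be in {1, 0, -1}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def masked(self, test_idx: Sequence[int]) -> "DiseaseGraph":
        """Copy with the given nodes' labels hidden (set to unlabeled)."""
        labels = self.labels.copy()
        labels[list(test_idx)] = UNLABELED
        return DiseaseGraph(self.node_ids, self.adjacency, self.features, labels)


def build_disease_graph(
    sim_matrix: np.ndarray,
    features: np.ndarray,
    labels: Sequence[int],
    node_ids: Sequence[str],
    edge_threshold: float = 0.0,
) -> DiseaseGraph:
    """Assemble the disease graph from a similarity matrix, features and labels.

    Off-diagonal similarities below ``edge_threshold`` are zeroed (the default
    0 keeps the dense weighted graph); the diagonal is zeroed, deferring the
    self-loop convention to the GCN operator.  Isolated nodes are kept.
    """
    sim = np.asarray(sim_matrix, dtype=float)
    n = len(node_ids)
    if sim.shape != (n, n):
        raise ValueError(f"similarity matrix shape {sim.shape} != ({n}, {n})")
    if np.asarray(features).shape[0] != n or len(labels) != n:
        raise ValueError("features/labels row count does not match node_ids")
    A = sim.copy()
    A[A < edge_threshold] = 0.0
    np.fill_diagonal(A, 0.0)
    return DiseaseGraph(tuple(node_ids), A, np.asarray(features, dtype=float), np.asarray(labels))
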