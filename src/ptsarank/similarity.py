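"""Gene-network-based disease similarity.

Two diseases are compared as two gene sets over a weighted gene functional
network whose edges carry log-likelihood scores (LLS).  Pairwise gene
similarity is the min-max-normalized LLS (1 for identical genes, 0 for
non-adjacent genes); a gene-to-set association is the best match into the
set; and the disease-pair similarity is the best-match average (BMA) over
both sets.

Two normalization modes are exposed.  ``"corrected"`` (the default) is the
standard min-max rescaling ``(lls - min) / (max - min)``.  ``"as_printed"``
evaluates ``(lls - min) / (max - lls)``, a variant that circulates in the
applied literature; it is non-monotone, unbounded, and singular when
``lls == max``, so it is retained only for fidelity audits and raises on
the singular input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Tuple

import numpy as np

_MODES = ("corrected", "as_printed")


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; expected one of {_MODES}")


def normalize_lls(lls: float, lls_min: float, lls_max: float, mode: str = "corrected") -> float:
    """Normalize a raw log-likelihood score to the unit interval.

    Parameters
    ----------
    lls
        Raw edge score, must satisfy ``lls_min <= lls <= lls_max``.
    lls_min, lls_max
        Global extremes of the network's edge scores, ``lls_min < lls_max``.
    mode
        ``"corrected"`` for ``(lls - min)/(max - min)``; ``"as_printed"``
        for ``(lls - min)/(max - lls)`` which raises at ``lls == lls_max``.
    """
    _check_mode(mode)
    if not lls_min < lls_max:
        raise ValueError(f"lls_min ({lls_min}) must be strictly below lls_max ({lls_max})")
    if not (lls_min <= lls <= lls_max):
        raise ValueError(f"lls {lls} outside [{lls_min}, {lls_max}]")
    if mode == "corrected":
        return (lls - lls_min) / (lls_max - lls_min)
    if lls == lls_max:
        raise ZeroDivisionError(
            "as_printed normalization divides by (lls_max - lls), which vanishes at "
            "the maximum score; use mode='corrected' for a well-defined rescaling"
        )
    return (lls - lls_min) / (lls_max - lls)


@dataclass(frozen=True)
class GeneNetwork:
    """Weighted undirected gene graph with raw LLS edge weights.

    Edges are stored once per unordered pair; lookups are symmetric.
    ``lls_min``/``lls_max`` are the global extremes over all edges, cached
    at construction because normalization is relative to the whole network.
    """

    edges: Mapping[FrozenSet[str], float]
    lls_min: float
    lls_max: float
    genes: Tuple[str, ...]

    @classmethod
    def from_edges(cls, edge_list: Iterable[Tuple[str, str, float]]) -> "GeneNetwork":
        """Build a network from ``(gene1, gene2, lls)`` triples.

        Self-edges are rejected; duplicate pairs with conflicting weights
        raise, duplicates with equal weight collapse to one edge.
        """
        edges: Dict[FrozenSet[str], float] = {}
        genes: set[str] = set()
        for a, b, w in edge_list:
            if a == b:
                raise ValueError(f"self-edge on gene {a!r} is not allowed")
            key = frozenset((a, b))
            w = float(w)
            if key in edges and edges[key] != w:
                raise ValueError(f"conflicting weights for edge ({a}, {b}): {edges[key]} vs {w}")
            edges[key] = w
            genes.update((a, b))
        if not edges:
            raise ValueError("gene network needs at least one edge")
        weights = list(edges.values())
        return cls(
            edges=edges,
            lls_min=min(weights),
            lls_max=max(weights),
            genes=tuple(sorted(genes)),
        )

    def lls(self, g_i: str, g_j: str) -> float | None:
        """Raw LLS of the edge (g_i, g_j), or None if absent."""
        return self.edges.get(frozenset((g_i, g_j)))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_triples(self) -> list[Tuple[str, str, float]]:
        """Sorted (gene1, gene2, lls) triples with gene1 < gene2."""
        out = []
        for key, w in self.edges.items():
            a, b = sorted(key)
            out.append((a, b, w))
        out.sort()
        return out


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Mapping from disease IDs to their associated gene sets.

    Genes need not be present in the gene network: an unannotated gene still
    matches itself (similarity 1) and contributes 0 against every other gene.
    """

    gene_sets: Mapping[str, FrozenSet[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "DiseaseGeneMap":
        sets: Dict[str, set] = {}
        for disease, gene in pairs:
            sets.setdefault(disease, set()).add(gene)
        return cls({d: frozenset(g) for d, g in sets.items()})

    @property
    def disease_ids(self) -> Tuple[str, ...]:
        return tuple(sorted(self.gene_sets))

    def genes_of(self, disease: str) -> FrozenSet[str]:
        return self.gene_sets[disease]

    def pairs(self) -> list[Tuple[str, str]]:
        return sorted((d, g) for d, gs in self.gene_sets.items() for g in gs)


def gene_pair_similarity(g_i: str, g_j: str, network: GeneNetwork, mode: str = "corrected") -> float:
    """Similarity of two genes: 1 if identical, normalized LLS if adjacent, else 0."""
    if g_i == g_j:
        return 1.0
    raw = network.lls(g_i, g_j)
    if raw is None:
        return 0.0
    return normalize_lls(raw, network.lls_min, network.lls_max, mode)


def gene_to_set_association(
    g: str, gene_set: Iterable[str], network: GeneNetwork, mode: str = "corrected"
) -> float:
    """Best match of gene ``g`` into ``gene_set``: max pairwise similarity."""
    members = list(gene_set)
    if not members:
        raise ValueError("gene set must be non-empty")
    return max(gene_pair_similarity(g, m, network, mode) for m in members)


def disease_pair_similarity(
    set1: Iterable[str], set2: Iterable[str], network: GeneNetwork, mode: str = "corrected"
) -> float:
    """Best-match-average similarity of two diseases viewed as gene sets.

    ``(sum_{g in G1} F(G2, g) + sum_{g in G2} F(G1, g)) / (|G1| + |G2|)``
    where F is the best-match association.  Symmetric by construction and
    bounded by [0, 1] in corrected mode.
    """
    g1 = list(set1)
    g2 = list(set2)
    if not g1 or not g2:
        raise ValueError("both gene sets must be non-empty")
    total = sum(gene_to_set_association(g, g2, network, mode) for g in g1)
    total += sum(gene_to_set_association(g, g1, network, mode) for g in g2)
    return total / (len(g1) + len(g2))


def _gene_sim_matrix(genes: Sequence[str], network: GeneNetwork, mode: str) -> np.ndarray:
    """Dense gene-by-gene similarity over the given gene universe."""
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    sim = np.zeros((n, n))
    np.fill_diagonal(sim, 1.0)
    for key, raw in network.edges.items():
        a, b = tuple(key)
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        val = normalize_lls(raw, network.lls_min, network.lls_max, mode)
        sim[ia, ib] = sim[ib, ia] = val
    return sim


def similarity_matrix(
    dmap: DiseaseGeneMap, network: GeneNetwork, mode: str = "corrected"
) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """Full disease-by-disease best-match-average similarity matrix.

    Returns the symmetric matrix with unit diagonal and the disease-ID order
    (sorted) labelling its rows and columns.  Vectorized via a dense
    gene-similarity lookup restricted to the genes in use; equivalent to
    calling :func:`disease_pair_similarity` per pair.
    """
    _check_mode(mode)
    ids = dmap.disease_ids
    if not ids:
        raise ValueError("disease-gene map is empty")
    for d in ids:
        if not dmap.genes_of(d):
            raise ValueError(f"disease {d!r} has an empty gene set")
    universe = sorted({g for d in ids for g in dmap.genes_of(d)})
    gindex = {g: i for i, g in enumerate(universe)}
    gene_sim = _gene_sim_matrix(universe, network, mode)
    idx_sets = [np.array([gindex[g] for g in sorted(dmap.genes_of(d))]) for d in ids]
    n = len(ids)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sub = gene_sim[np.ix_(idx_sets[i], idx_sets[j])]
            val = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (
                len(idx_sets[i]) + len(idx_sets[j])
            )
            out[i, j] = out[j, i] = val
    return out, ids
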