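"""Synthetic scenario generator with planted positive-class structure.

Emulates the three inputs of the real pipeline — a weighted gene functional
network, disease-gene associations, and disease-protein annotations — with
controllable statistical structure, so every downstream stage can be tested
without external database downloads.

The positive class is planted through the same two channels the pipeline
combines:

* **shared genes**: positive diseases draw a ``signal_strength`` fraction of
  their gene set from a small common pool, which elevates their pairwise
  best-match-average similarity and therefore clusters them in the disease
  graph;
* **informative proteins**: a ``signal_strength``-scaled fraction of proteins
  is present with a higher probability in positives than in unknowns, which
  separates the classes in raw feature space.

At ``signal_strength = 0`` both channels vanish and positives are
statistically indistinguishable from unknowns.

One master seed spawns independent per-generator substreams
(``numpy.random.SeedSequence`` children), so adding a generator never
perturbs the outputs of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .disease_graph import (
    DiseaseProteinMap,
    build_disease_graph,
    encode_protein_features,
    select_frequent_proteins,
)
from .similarity import DiseaseGeneMap, GeneNetwork, similarity_matrix

# substream indices of the master seed; append-only so outputs stay stable
_STREAM_NETWORK = 0
_STREAM_GENE_MAP = 1
_STREAM_PROTEIN_MAP = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic prioritization scenario.

    Defaults mirror a desk-scale version of the real use case: 123 diseases
    of which 23 are known positives (one fold per positive in the
    leave-one-out design), a sparse gene network with a positive-valued
    log-likelihood score range, gene sets of 5-15 genes per disease, and a
    sparse binary protein panel in which only a minority of proteins carry
    label signal.
    """

    n_genes: int = 300
    n_diseases: int = 123
    n_positives: int = 23
    n_proteins: int = 64
    edge_density: float = 0.05
    lls_range: Tuple[float, float] = (0.5, 4.0)
    positive_gene_pool: int = 30
    signal_strength: float = 0.9
    genes_per_disease: Tuple[int, int] = (5, 15)
    seed: int = 0
    # protein channel: informative proteins appear with probability
    # p_neg + signal_strength * (p_pos - p_neg) in positives, p_neg otherwise
    protein_p_pos: float = 0.5
    protein_p_neg: float = 0.1
    informative_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        for name in ("n_diseases", "n_positives", "n_proteins", "positive_gene_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_positives > self.n_diseases:
            raise ValueError("n_positives must not exceed n_diseases")
        if self.positive_gene_pool > self.n_genes:
            raise ValueError("positive_gene_pool must not exceed n_genes")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must be in (0, 1]")
        if not self.lls_range[0] < self.lls_range[1]:
            raise ValueError("lls_range must satisfy min < max")
        low, high = self.genes_per_disease
        if low < 1 or low > high:
            raise ValueError("genes_per_disease must satisfy 1 <= low <= high")
        if high > self.n_genes:
            raise ValueError("genes_per_disease.high must not exceed n_genes")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")

    def stream(self, index: int) -> np.random.Generator:
        """Independent child RNG stream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(index,)))

    @property
    def gene_ids(self) -> Tuple[str, ...]:
        width = len(str(self.n_genes - 1))
        return tuple(f"g{i:0{width}d}" for i in range(self.n_genes))

    @property
    def disease_ids(self) -> Tuple[str, ...]:
        width = len(str(self.n_diseases - 1))
        return tuple(f"d{i:0{width}d}" for i in range(self.n_diseases))

    @property
    def protein_ids(self) -> Tuple[str, ...]:
        width = len(str(self.n_proteins - 1))
        return tuple(f"p{i:0{width}d}" for i in range(self.n_proteins))

    @property
    def positive_ids(self) -> Tuple[str, ...]:
        # planted positives are the first n_positives disease IDs
        return self.disease_ids[: self.n_positives]


def simulate_gene_network(config: SimulationConfig) -> GeneNetwork:
    """Erdős–Rényi-style gene graph with uniform LLS edge weights.

    Samples ``round(edge_density * n_genes * (n_genes - 1) / 2)`` distinct
    undirected edges; every weight is uniform within ``lls_range``.
    """
    rng = config.stream(_STREAM_NETWORK)
    genes = config.gene_ids
    n = config.n_genes
    n_pairs = n * (n - 1) // 2
    n_edges = max(1, round(config.edge_density * n_pairs))
    rows, cols = np.triu_indices(n, k=1)
    chosen = np.sort(rng.choice(n_pairs, size=n_edges, replace=False))
    lo, hi = config.lls_range
    weights = rng.uniform(lo, hi, size=n_edges)
    triples = [(genes[rows[k]], genes[cols[k]], float(w)) for k, w in zip(chosen, weights)]
    return GeneNetwork.from_edges(triples)


def simulate_disease_gene_map(config: SimulationConfig, network: GeneNetwork) -> DiseaseGeneMap:
    """Gene sets per disease, with positives biased toward a shared pool.

    Each disease draws a set size uniformly within ``genes_per_disease``.
    A positive disease takes ``round(signal_strength * size)`` genes from the
    shared ``positive_gene_pool`` (without replacement, capped at pool size)
    and the remainder from the other genes; unknowns draw uniformly from all
    genes.
    """
    rng = config.stream(_STREAM_GENE_MAP)
    genes = np.array(config.gene_ids)
    pool = rng.choice(config.n_genes, size=config.positive_gene_pool, replace=False)
    low, high = config.genes_per_disease
    positives = set(config.positive_ids)
    sets: Dict[str, frozenset] = {}
    for d in config.disease_ids:
        size = int(rng.integers(low, high + 1))
        if d in positives:
            k_pool = min(round(config.signal_strength * size), len(pool), size)
            idx_pool = rng.choice(pool, size=k_pool, replace=False)
            rest = size - k_pool
            remaining = np.setdiff1d(np.arange(config.n_genes), idx_pool)
            idx_rest = rng.choice(remaining, size=rest, replace=False) if rest else np.array([], int)
            idx = np.concatenate([idx_pool, idx_rest]).astype(int)
        else:
            idx = rng.choice(config.n_genes, size=size, replace=False)
        sets[d] = frozenset(genes[idx])
    return DiseaseGeneMap(sets)


def simulate_disease_protein_map(config: SimulationConfig) -> DiseaseProteinMap:
    """Binary disease-by-protein annotations with label-informative proteins.

    ``round(signal_strength * informative_fraction * n_proteins)`` proteins
    are informative: positives carry them with probability
    ``p_neg + signal_strength * (p_pos - p_neg)``, unknowns with ``p_neg``.
    All other proteins appear with the background probability ``p_neg`` in
    both classes.
    """
    rng = config.stream(_STREAM_PROTEIN_MAP)
    proteins = np.array(config.protein_ids)
    n_informative = round(config.signal_strength * config.informative_fraction * config.n_proteins)
    informative = rng.choice(config.n_proteins, size=n_informative, replace=False)
    p_base = config.protein_p_neg
    p_signal = p_base + config.signal_strength * (config.protein_p_pos - p_base)
    prob = np.full((config.n_diseases, config.n_proteins), p_base)
    prob[: config.n_positives, informative] = p_signal
    incidence = rng.random(prob.shape) < prob
    sets = {
        d: frozenset(proteins[np.flatnonzero(incidence[i])])
        for i, d in enumerate(config.disease_ids)
    }
    return DiseaseProteinMap(sets, tuple(config.protein_ids))


def simulate_scenario(
    config: SimulationConfig,
) -> Tuple[GeneNetwork, DiseaseGeneMap, DiseaseProteinMap, Dict[str, int]]:
    """All three pipeline inputs plus labels, from one master seed.

    Labels mark exactly ``n_positives`` diseases (the planted positives) as 1
    and the rest as 0 (unknown).
    """
    network = simulate_gene_network(config)
    gene_map = simulate_disease_gene_map(config, network)
    protein_map = simulate_disease_protein_map(config)
    positives = set(config.positive_ids)
    labels = {d: int(d in positives) for d in config.disease_ids}
    return network, gene_map, protein_map, labels


def simulate_disease_graph(
    config: SimulationConfig,
    min_diseases: int = 1,
    edge_threshold: float = 0.0,
    mode: str = "corrected",
):
    """Convenience: simulate a scenario and assemble the labeled disease graph.

    Runs similarity → protein filter → feature encoding → graph assembly with
    the sorted disease-ID node order.
    """
    network, gene_map, protein_map, labels = simulate_scenario(config)
    sim, ids = similarity_matrix(gene_map, network, mode=mode)
    selected = select_frequent_proteins(protein_map, min_diseases)
    X = encode_protein_features(protein_map, selected, disease_ids=ids)
    y = [labels[d] for d in ids]
    return build_disease_graph(sim, X, y, ids, edge_threshold=edge_threshold)
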