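"""Readers and writers for the pipeline's plain-text exchange formats.

All tabular artifacts are TSV with explicit identifier headers so every
matrix is auditable without positional conventions: gene-network edge
lists, disease-gene and disease-protein association tables, label lists,
similarity/adjacency matrices, sparse feature triplets, embeddings,
per-disease scores, and JSON reports.  Run configuration is YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .disease_graph import DiseaseGraph, DiseaseProteinMap
from .similarity import DiseaseGeneMap, GeneNetwork


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read a gene-network TSV (gene1 TAB gene2 TAB lls; header optional).

    Reciprocal duplicates with equal weight collapse to one undirected edge;
    conflicting duplicate weights raise with the offending line number.
    """
    path = Path(path)
    edges: Dict[frozenset, Tuple[float, int]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            a, b, w = parts
            if lineno == 1 and not _is_float(w):
                continue  # header row
            if not _is_float(w):
                raise ValueError(f"{path}:{lineno}: weight {w!r} is not numeric")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-edge on {a!r}")
            key = frozenset((a, b))
            weight = float(w)
            if key in edges and edges[key][0] != weight:
                prev_w, prev_line = edges[key]
                raise ValueError(
                    f"{path}:{lineno}: edge ({a}, {b}) weight {weight} conflicts with "
                    f"{prev_w} on line {prev_line}"
                )
            edges.setdefault(key, (weight, lineno))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return GeneNetwork.from_edges(
        (min(k), max(k), w) for k, (w, _) in edges.items()
    )


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    rows = network.edge_triples()
    pd.DataFrame(rows, columns=["gene1", "gene2", "lls"]).to_csv(path, sep="\t", index=False)


def read_disease_gene_map(path: str | Path) -> DiseaseGeneMap:
    """Disease-gene TSV (disease TAB gene; header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["disease", "gene"], dtype=str)
    if df.iloc[0, 0] == "disease" and df.iloc[0, 1] == "gene":
        df = df.iloc[1:]
    return DiseaseGeneMap.from_pairs(df.itertuples(index=False))


def write_disease_gene_map(dmap: DiseaseGeneMap, path: str | Path) -> None:
    pd.DataFrame(dmap.pairs(), columns=["disease", "gene"]).to_csv(path, sep="\t", index=False)


def read_disease_protein_map(path: str | Path) -> DiseaseProteinMap:
    """Disease-protein TSV (disease TAB protein; header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["disease", "protein"], dtype=str)
    if df.iloc[0, 0] == "disease" and df.iloc[0, 1] == "protein":
        df = df.iloc[1:]
    return DiseaseProteinMap.from_pairs(df.itertuples(index=False))


def write_disease_protein_map(dmap: DiseaseProteinMap, path: str | Path) -> None:
    pd.DataFrame(dmap.pairs(), columns=["disease", "protein"]).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> Tuple[str, ...]:
    """Positive-disease list: one disease ID per line."""
    with Path(path).open() as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_labels(positives: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{d}\n" for d in sorted(positives)))


def write_matrix(matrix: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    """Square matrix with disease IDs as header row and first column."""
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", index_label="disease"
    )


def read_matrix(path: str | Path) -> Tuple[np.ndarray, Tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), tuple(df.index.astype(str))


def write_feature_triplets(
    features: np.ndarray, node_ids: Sequence[str], feature_ids: Sequence[str], path: str | Path
) -> None:
    """Sparse triplet TSV (disease TAB feature TAB value) of nonzero entries."""
    rows, cols = np.nonzero(np.asarray(features))
    pd.DataFrame(
        {
            "disease": [node_ids[i] for i in rows],
            "feature": [feature_ids[j] for j in cols],
            "value": np.asarray(features)[rows, cols],
        }
    ).to_csv(path, sep="\t", index=False)


def write_graph_bundle(
    graph: DiseaseGraph, feature_ids: Sequence[str], outdir: str | Path
) -> None:
    """Adjacency TSV + sparse feature triplets + node metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(graph.adjacency, graph.node_ids, outdir / "adjacency.tsv")
    write_feature_triplets(graph.features, graph.node_ids, feature_ids, outdir / "features.tsv")
    pd.DataFrame({"disease": graph.node_ids, "label": graph.labels}).to_csv(
        outdir / "nodes.tsv", sep="\t", index=False
    )


def write_embeddings(embeddings: np.ndarray, node_ids: Sequence[str], path: str | Path) -> None:
    cols = [f"dim{j}" for j in range(embeddings.shape[1])]
    pd.DataFrame(embeddings, index=list(node_ids), columns=cols).to_csv(
        path, sep="\t", index_label="disease"
    )


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Scores-TSV exchange format (disease TAB score [...]), e.g. from external baselines."""
    return pd.read_csv(path, sep="\t")


def write_report(report: Dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> Dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
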