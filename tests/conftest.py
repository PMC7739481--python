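import numpy as np
import pytest

from ptsarank.similarity import DiseaseGeneMap, GeneNetwork


@pytest.fixture
def toy_network() -> GeneNetwork:
    """Five genes, LLS range [2, 10]; (a,b) normalizes to 0.375 corrected."""
    return GeneNetwork.from_edges(
        [
            ("a", "b", 5.0),
            ("a", "c", 2.0),
            ("b", "c", 10.0),
            ("c", "d", 6.0),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_gene_map(rng: np.random.Generator, genes, n_diseases: int) -> DiseaseGeneMap:
    genes = list(genes)
    sets = {}
    for i in range(n_diseases):
        size = int(rng.integers(1, min(5, len(genes)) + 1))
        chosen = rng.choice(genes, size=size, replace=False)
        sets[f"d{i:02d}"] = frozenset(chosen)
    return DiseaseGeneMap(sets)
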