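import numpy as np
import pytest

from hexspot import preprocess
from hexspot.synthdata import SimConfig, simulate_st_dataset


SMALL_SIM = dict(rows=20, cols=15, n_genes=150, seed=11)


@pytest.fixture(scope="session")
def st_sim():
    """One small simulated capture area (300 spots, 150 genes) shared by
    read-only tests."""
    return simulate_st_dataset(SimConfig(**SMALL_SIM))


@pytest.fixture(scope="session")
def st_norm(st_sim):
    sm, _, _ = st_sim
    return preprocess.normalize(sm)


@pytest.fixture(scope="session")
def st_graph(st_sim):
    _, lattice, _ = st_sim
    return preprocess.build_neighbor_graph(lattice)


@pytest.fixture(scope="session")
def st_degs(st_norm, st_sim):
    sm, _, _ = st_sim
    return preprocess.find_cluster_degs(st_norm, sm.annotations["cluster"])


def enumeration_hypergeom_tail(overlap, set1, set2, universe):
    """Brute-force P(X >= overlap): enumerate every draw of `set2` elements
    from a universe whose first `set1` elements are marked."""
    from itertools import combinations

    hits = total = 0
    for combo in combinations(range(universe), set2):
        total += 1
        if sum(1 for e in combo if e < set1) >= overlap:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def hypergeom_oracle():
    return enumeration_hypergeom_tail
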