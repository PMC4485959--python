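import itertools

import numpy as np
import pandas as pd
import pytest

from phylofd import (
    Phylogeny,
    read_newick,
    simulate_bm_trait,
    simulate_yule_tree,
)


@pytest.fixture
def cherry():
    """Smallest chronogram: two tips at depth 1."""
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — depth-2 ultrametric tree."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4():
    """Four-tip star phylogeny, depth 1."""
    return read_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def yule10():
    return simulate_yule_tree(10, seed=42)


@pytest.fixture
def yule61():
    return simulate_yule_tree(61, seed=7)


def brute_force_patristic(phy: Phylogeny) -> pd.DataFrame:
    """Independent oracle: shortest tip-to-tip path sums on the tree graph."""
    import networkx as nx

    G = nx.Graph()
    ids = {}
    for i, node in enumerate(phy.tree.preorder_node_iter()):
        ids[node] = i
        if node.parent_node is not None:
            G.add_edge(ids[node.parent_node], i, weight=node.edge.length)
    leaves = {l.taxon.label: ids[l] for l in phy.tree.leaf_node_iter()}
    labels = phy.tip_labels
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        d = nx.shortest_path_length(G, leaves[a], leaves[b], weight="weight")
        D.loc[a, b] = D.loc[b, a] = d
    return D


def brute_force_vcv(phy: Phylogeny) -> pd.DataFrame:
    """Independent oracle: per-pair shared root-to-MRCA path length via
    explicit ancestor-path intersection."""
    paths = {}
    for leaf in phy.tree.leaf_node_iter():
        chain = []
        node = leaf
        while node.parent_node is not None:
            chain.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    labels = phy.tip_labels
    V = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            shared = set(id(n) for n in paths[a]) & set(id(n) for n in paths[b])
            V.loc[a, b] = sum(n.edge.length for n in paths[a] if id(n) in shared)
    return V


def brute_force_moran(x: np.ndarray, W: np.ndarray) -> float:
    """Direct double-sum evaluation of Moran's I."""
    n = len(x)
    xbar = x.mean()
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            S0 += W[i, j]
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / S0 * num / den


def brute_force_fdis(abund: dict[str, float], Z: pd.DataFrame) -> float:
    """Direct centroid-and-distance evaluation of functional dispersion."""
    species = [s for s, a in abund.items() if a > 0]
    if len(species) == 1:
        return 0.0
    total = sum(abund[s] for s in species)
    k = Z.shape[1]
    centroid = [sum(abund[s] * Z.loc[s].iloc[j] for s in species) / total for j in range(k)]
    out = 0.0
    for s in species:
        d = sum((Z.loc[s].iloc[j] - centroid[j]) ** 2 for j in range(k)) ** 0.5
        out += abund[s] * d
    return out / total


def brute_force_psv(species: list[str], C: pd.DataFrame) -> float:
    """Direct 1 − mean off-diagonal correlation."""
    if len(species) == 1:
        return 0.0
    vals = [
        C.loc[a, b]
        for a in species
        for b in species
        if a != b
    ]
    return 1.0 - sum(vals) / len(vals)


@pytest.fixture
def bm_trait(yule61):
    return simulate_bm_trait(yule61, sigma2=1.0, lambda_true=1.0, seed=11)
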