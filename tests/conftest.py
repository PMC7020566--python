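from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from bnclust import TreeNetwork


def tree_from_edges(n: int, edges) -> TreeNetwork:
    """TreeNetwork from integer index edges, nodes named n0..n{n-1}."""
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    return TreeNetwork(
        nodes=tuple(f"n{i}" for i in range(n)),
        edges=frozenset((min(i, j), max(i, j)) for i, j in edges),
        adjacency=adj,
    )


def random_tree(n: int, rng: np.random.Generator) -> TreeNetwork:
    """Uniform random labeled tree (random Pruefer sequence)."""
    if n == 2:
        return tree_from_edges(2, [(0, 1)])
    seq = rng.integers(0, n, size=n - 2).tolist()
    g = nx.from_prufer_sequence(seq)
    return tree_from_edges(n, g.edges())


def star_tree(n: int) -> TreeNetwork:
    return tree_from_edges(n, [(0, i) for i in range(1, n)])


def path_tree(n: int) -> TreeNetwork:
    return tree_from_edges(n, [(i, i + 1) for i in range(n - 1)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
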