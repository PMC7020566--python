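"""Construction of tree-structured functional brain networks.

A subject's regional BOLD time series are turned into a fully connected
Pearson-correlation network, which is then reduced to its spanning tree by
Kruskal's procedure run in *descending* weight order — i.e. the loopless
backbone linking all regions through their strongest correlations.  The
tree keeps the core connectivity skeleton while avoiding the arbitrary
threshold needed to binarize a dense correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger("bnclust")

#: The 16 bilateral AAL regions conventionally forming the default mode
#: network, suffixed .L/.R — 32 node labels used purely for labeling.
DMN_REGIONS = (
    "ORBsup", "MFG", "ORBmid", "REC", "ACG", "PCG", "PCUN", "HIP",
    "PHG", "IPL", "ANG", "STG", "TPOsup", "MTG", "TPOmid", "ITG",
)
DMN_NODES = tuple(f"{r}.{side}" for r in DMN_REGIONS for side in ("L", "R"))


def default_region_names(n: int) -> list[str]:
    """Generated node labels R001..Rnnn for inputs without headers."""
    width = max(3, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Regional time series: T time points x n regions.

    Rejected on construction when fewer than 3 time points are present
    (Pearson correlation is degenerate) or when any region has zero
    variance (correlation undefined).
    """

    values: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        if values.ndim != 2:
            raise ValueError("time-series values must be a 2-D matrix")
        t, n = values.shape
        if len(self.region_names) != n:
            raise ValueError(
                f"{len(self.region_names)} region names for {n} columns"
            )
        if t < 3:
            raise ValueError(
                f"need at least 3 time points for Pearson correlation, got {t}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contain non-finite values")
        sd = values.std(axis=0)
        dead = np.flatnonzero(sd == 0.0)
        if dead.size:
            names = ", ".join(self.region_names[i] for i in dead)
            raise ValueError(
                f"zero-variance region(s): {names}; correlation undefined"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric connectivity network; the diagonal is stored as zero."""

    weights: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.region_names) != w.shape[0]:
            raise ValueError("region_names length must match matrix size")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class TreeNetwork:
    """A spanning tree: n nodes, exactly n-1 edges, connected, acyclic.

    ``edges`` holds unordered index pairs (i, j) with i < j; ``adjacency``
    is the consistent binary matrix.  ``edge_weights`` optionally carries
    the source-network weight of each tree edge (export only; downstream
    similarity computations use the unweighted topology).
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    adjacency: np.ndarray = field(repr=False)
    edge_weights: dict[tuple[int, int], float] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        edges = frozenset(
            (min(i, j), max(i, j)) for i, j in self.edges
        )
        object.__setattr__(self, "edges", edges)
        n = len(self.nodes)
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        expected = np.zeros((n, n))
        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid edge ({i}, {j}) for {n} nodes")
            expected[i, j] = expected[j, i] = 1.0
        if not np.array_equal(adj, expected):
            raise ValueError("adjacency inconsistent with edge set")
        if len(edges) != n - 1:
            raise ValueError(
                f"a spanning tree on {n} nodes needs {n - 1} edges, "
                f"got {len(edges)}"
            )
        g = self.to_graph()
        if not nx.is_connected(g):
            raise ValueError("tree network is not connected")
        # n-1 edges + connected => acyclic, but check explicitly
        if not nx.is_forest(g):
            raise ValueError("tree network contains a cycle")
        adj = expected
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_graph(self) -> nx.Graph:
        """Unweighted networkx view (nodes are integer indices)."""
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g


def correlation_network(ts: TimeSeriesMatrix) -> WeightedNetwork:
    """Fully connected Pearson-correlation network of a subject.

    Every pair of regional time series is correlated; the diagonal is
    zeroed because self-connections carry no information downstream.
    """
    corr = np.corrcoef(ts.values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return WeightedNetwork(weights=corr, region_names=ts.region_names)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_spanning_tree(net: WeightedNetwork) -> TreeNetwork:
    """Spanning tree by Kruskal's procedure in descending weight order.

    Edges are sorted by decreasing weight (ties broken lexicographically
    by node-index pair for determinism) and greedily added, skipping any
    edge that would close a loop, until all nodes are linked — the
    maximum-weight spanning tree of the connectivity network.  Negative
    weights are kept as-is and simply sort last.  Entries that are exactly
    zero are treated as absent edges.
    """
    n = net.n_nodes
    w = net.weights
    iu, ju = np.triu_indices(n, k=1)
    present = w[iu, ju] != 0.0
    candidates = sorted(
        zip(iu[present], ju[present]),
        key=lambda e: (-w[e[0], e[1]], e[0], e[1]),
    )

    uf = _UnionFind(n)
    chosen: list[tuple[int, int]] = []
    for i, j in candidates:
        if uf.union(int(i), int(j)):
            chosen.append((int(i), int(j)))
            if len(chosen) == n - 1:
                break

    if len(chosen) != n - 1:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((int(i), int(j)) for i, j in zip(iu[present], ju[present]))
        comps = [sorted(net.region_names[k] for k in c)
                 for c in nx.connected_components(g)]
        raise ValueError(
            f"input network is disconnected; components: {comps}"
        )

    adj = np.zeros((n, n))
    for i, j in chosen:
        adj[i, j] = adj[j, i] = 1.0
    weights = {(i, j): float(w[i, j]) for i, j in chosen}
    return TreeNetwork(
        nodes=net.region_names,
        edges=frozenset(chosen),
        adjacency=adj,
        edge_weights=weights,
    )
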