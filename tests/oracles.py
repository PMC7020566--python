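"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration and
explicit loops — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_max_spanning_tree(
    n: int, weights: np.ndarray
) -> frozenset[tuple[int, int]]:
    """Argmax-total-weight spanning tree by enumerating all edge subsets."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if weights[i, j] != 0.0]
    best, best_w = None, -math.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph(subset)
        g.add_nodes_from(range(n))
        if not nx.is_connected(g):
            continue
        total = sum(weights[i, j] for i, j in subset)
        if total > best_w:
            best_w, best = total, frozenset(subset)
    assert best is not None, "no spanning tree exists"
    return best


def exhaustive_betweenness(graph: nx.Graph) -> np.ndarray:
    """Normalized betweenness by enumerating every ordered pair's paths."""
    n = graph.number_of_nodes()
    nodes = sorted(graph.nodes())
    values = np.zeros(n)
    for idx, i in enumerate(nodes):
        total = 0.0
        for h, j in itertools.permutations(nodes, 2):
            if i in (h, j):
                continue
            paths = list(nx.all_shortest_paths(graph, h, j))
            through = sum(1 for p in paths if i in p)
            total += through / len(paths)
        values[idx] = total / ((n - 1) * (n - 2))
    return values


def naive_subnetwork_kernel(
    adj_g: np.ndarray,
    adj_h: np.ndarray,
    h: int,
    d: int,
    ridge: float,
    variant: str = "as_printed",
) -> float:
    """Loop-based sub-network kernel with explicit covariances/log-dets."""
    n = adj_g.shape[0]
    total = 0.0
    for i in range(n):
        per_node = 0.0
        for j in range(1, h + 1):
            c_g = _naive_descriptor(adj_g, i, j, d, ridge)
            c_h = _naive_descriptor(adj_h, i, j, d, ridge)
            a = (c_g + c_h) / 2.0
            ld = (math.log(np.linalg.det(a))
                  - _det_weight(variant) * math.log(np.linalg.det(c_g))
                  - _det_weight(variant) * math.log(np.linalg.det(c_h)))
            per_node += math.exp(-0.5 * ld)
        total += per_node / h
    return total / n


def _det_weight(variant: str) -> float:
    return 1.0 if variant == "as_printed" else 0.5


def _naive_descriptor(
    adj: np.ndarray, center: int, radius: int, d: int, ridge: float
) -> np.ndarray:
    g = nx.from_numpy_array(adj)
    dist = nx.single_source_shortest_path_length(g, center)
    members = sorted(v for v, s in dist.items() if s <= radius)
    w = adj[np.ix_(members, members)]
    n_sub = len(members)
    us = []
    v = np.ones(n_sub)
    for _ in range(d):
        v = w @ v
        us.append(n_sub * v / np.abs(v).sum())
    cov = np.empty((d, d))
    for a in range(d):
        for b in range(d):
            xa, xb = us[a], us[b]
            cov[a, b] = np.sum(
                (xa - xa.mean()) * (xb - xb.mean())
            ) / (n_sub - 1)
    return cov + ridge * np.eye(d)


def brute_force_consistency(labels: np.ndarray, classes: np.ndarray) -> float:
    """Max matched count over all one-to-one cluster/class pairings."""
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    cluster_ids = sorted(set(labels.tolist()))
    class_ids = sorted(set(classes.tolist()))
    short, long_ = (cluster_ids, class_ids)
    swap = len(cluster_ids) > len(class_ids)
    if swap:
        short, long_ = class_ids, cluster_ids
    best = 0
    for assignment in itertools.permutations(long_, len(short)):
        matched = 0
        for s_id, l_id in zip(short, assignment):
            if swap:
                matched += int(np.sum((classes == s_id) & (labels == l_id)))
            else:
                matched += int(np.sum((labels == s_id) & (classes == l_id)))
        best = max(best, matched)
    return best / labels.size
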