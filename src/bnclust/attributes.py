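"""Node-attribute similarity between brain networks.

The attribute of interest is normalized betweenness centrality: for node
i, the fraction of ordered pairs (h, j) of other nodes whose shortest
path runs through i, divided by (n-1)(n-2).  In a spanning tree every
pair is joined by a unique path, so the measure reduces to simple path
counting; hubs score near 1, leaves score exactly 0.  Two networks are
compared by the cosine of their betweenness vectors, which is in [0, 1]
because betweenness is nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import TreeNetwork


@dataclass(frozen=True)
class BetweennessVector:
    """Per-node normalized betweenness, ordered like the network's nodes."""

    values: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_names", tuple(self.node_names))
        if v.ndim != 1 or v.size != len(self.node_names):
            raise ValueError("betweenness vector/node-name length mismatch")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("betweenness values must lie in [0, 1]")


def node_betweenness(tree: TreeNetwork | nx.Graph) -> BetweennessVector:
    """Normalized betweenness centrality of every node.

    Computed on the unweighted topology.  The shortest-path-count ratio
    in the definition is retained, so the operation is also valid on
    general graphs where pairs may have several shortest paths; on a tree
    the ratio is always 0 or 1.

    Parameters
    ----------
    tree
        A ``TreeNetwork`` (or any connected ``nx.Graph`` with at least 3
        nodes, integer-indexed 0..n-1).
    """
    if isinstance(tree, TreeNetwork):
        graph = tree.to_graph()
        names = tree.nodes
    else:
        graph = tree
        names = tuple(str(v) for v in sorted(graph.nodes()))
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError(
            f"betweenness normalization needs n >= 3 nodes, got {n}"
        )
    # normalized=True divides the ordered-pair path count by (n-1)(n-2)
    bc = nx.betweenness_centrality(graph, normalized=True)
    values = np.array([bc[i] for i in sorted(graph.nodes())])
    return BetweennessVector(values=values, node_names=names)


def attribute_similarity(
    b_g: BetweennessVector | np.ndarray, b_h: BetweennessVector | np.ndarray
) -> float:
    """Cosine similarity of two betweenness vectors.

    Equals 1 for identical (nonzero) vectors and 0 for orthogonal ones;
    invariant to common positive rescaling.  An all-zero vector is
    rejected (the cosine is undefined; a tree with n >= 3 always has an
    internal node, so this cannot occur for valid inputs).
    """
    x = np.asarray(b_g.values if isinstance(b_g, BetweennessVector) else b_g,
                   dtype=float)
    y = np.asarray(b_h.values if isinstance(b_h, BetweennessVector) else b_h,
                   dtype=float)
    if x.shape != y.shape:
        raise ValueError("betweenness vectors have different lengths")
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0.0 or ny_ == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(np.dot(x, y) / (nx_ * ny_))


def attribute_similarity_matrix(trees: list[TreeNetwork]) -> "np.ndarray":
    """All pairwise attribute similarities of a cohort.

    Returns an N x N symmetric matrix with unit diagonal.  All networks
    must share node count and node ordering (same brain parcellation).
    """
    if not trees:
        raise ValueError("empty cohort")
    ref = trees[0].nodes
    for idx, t in enumerate(trees):
        if t.nodes != ref:
            raise ValueError(
                f"network {idx} has a different node set/order than network 0"
            )
    vectors = np.vstack([node_betweenness(t).values for t in trees])
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    unit = vectors / norms
    sim = unit @ unit.T
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim
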