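"""Sub-network kernel: multi-level structural similarity of networks.

For every node of a network, nested sub-networks are taken as the induced
subgraphs of the hop-distance balls of radius j = 1..h around that node.
Each sub-network is summarized by a Krylov covariance descriptor: apply
the adjacency matrix W repeatedly to the all-ones vector e, l1-normalize
and rescale each power vector

    u_i = N * W^i e / ||W^i e||_1 ,   i = 1..d,

(N the sub-network's node count, so the entries of u_i average to 1) and
take the d x d sample covariance of {u_1..u_d} across node positions.  A
small ridge on the diagonal keeps the descriptor positive definite —
covariances of regular or very small sub-networks are otherwise singular.

Two same-node, same-radius sub-networks G_i^j, H_i^j with descriptors
C_G, C_H are compared through their log-determinants with A = (C_G+C_H)/2:

    as_printed:    g = exp(-1/2 [log|A| - log|C_G| - log|C_H|])
    s_divergence:  g = exp(-1/2 [log|A| - 1/2 log|C_G| - 1/2 log|C_H|])

The ``s_divergence`` variant is the symmetric Stein/log-det divergence
kernel, bounded by 1 with unit self-similarity; ``as_printed`` (the
default) omits the square roots in the denominator, so self-similarity
is |C|^(1/2) and a final normalization s(X,Y)/sqrt(s(X,X)s(Y,Y)) is
applied to the cohort matrix.  The kernel of two networks is the mean of
g over all nodes and radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import TreeNetwork

DEFAULT_RIDGE = 1e-6
KERNEL_VARIANTS = ("as_printed", "s_divergence")
SUBGRAPH_WEIGHTS = ("binary", "weighted")


def _tree_weight_matrix(tree: TreeNetwork, subgraph_weights: str) -> np.ndarray:
    """Adjacency used inside descriptors: binary, or source edge weights."""
    if subgraph_weights not in SUBGRAPH_WEIGHTS:
        raise ValueError(f"unknown subgraph_weights {subgraph_weights!r}")
    if subgraph_weights == "binary":
        return tree.adjacency
    if tree.edge_weights is None:
        raise ValueError(
            "subgraph_weights='weighted' requires a tree with edge weights"
        )
    n = tree.n_nodes
    w = np.zeros((n, n))
    for (i, j), weight in tree.edge_weights.items():
        w[i, j] = w[j, i] = weight
    return w


@dataclass(frozen=True)
class SubNetworkSet:
    """Nested induced subgraphs of radii 1..h around one node."""

    node_index: int
    node_sets: tuple[tuple[int, ...], ...]     # radius j = 1..h
    adjacencies: tuple[np.ndarray, ...]        # binary, same order as node_sets

    @property
    def h(self) -> int:
        return len(self.node_sets)


@dataclass(frozen=True)
class KrylovCovariance:
    """d x d covariance of normalized power-iteration vectors (+ ridge I)."""

    matrix: np.ndarray
    d: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.d, self.d):
            raise ValueError("covariance matrix shape does not match d")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        m = (m + m.T) / 2.0
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)


def extract_subnetworks(
    tree: TreeNetwork, node_index: int, h: int
) -> SubNetworkSet:
    """Nested hop-distance-ball subgraphs of radii 1..h around a node.

    Node sets grow monotonically with the radius; once the radius reaches
    the eccentricity of the node the ball is the whole network.
    """
    if h < 1:
        raise ValueError(f"radius bound h must be >= 1, got {h}")
    n = tree.n_nodes
    if not 0 <= node_index < n:
        raise ValueError(f"node index {node_index} out of range for {n} nodes")
    graph = tree.to_graph()
    dist = nx.single_source_shortest_path_length(graph, node_index, cutoff=h)
    node_sets = []
    adjacencies = []
    for j in range(1, h + 1):
        members = tuple(sorted(v for v, s in dist.items() if s <= j))
        idx = np.asarray(members)
        sub_adj = tree.adjacency[np.ix_(idx, idx)].copy()
        node_sets.append(members)
        adjacencies.append(sub_adj)
    return SubNetworkSet(
        node_index=node_index,
        node_sets=tuple(node_sets),
        adjacencies=tuple(adjacencies),
    )


def krylov_covariance(
    adjacency: np.ndarray, d: int, ridge: float = DEFAULT_RIDGE
) -> KrylovCovariance:
    """Krylov covariance descriptor of one sub-network.

    Forms u_i = N * W^i e / ||W^i e||_1 for i = 1..d and returns their
    sample covariance across node positions (denominator N - 1), with
    ridge * I added to guarantee positive definiteness.  For a k-regular
    sub-network every u_i is the constant vector, so the descriptor is
    exactly ridge * I.
    """
    w = np.asarray(adjacency, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    n_sub = w.shape[0]
    if n_sub < 2:
        raise ValueError("sub-network must contain at least 2 nodes")
    if d < 1:
        raise ValueError(f"power-iteration count d must be >= 1, got {d}")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    vectors = np.empty((d, n_sub))
    v = np.ones(n_sub)
    for i in range(d):
        v = w @ v
        l1 = np.abs(v).sum()
        if l1 == 0.0:
            raise ValueError(
                "power vector vanished (empty adjacency); descriptor undefined"
            )
        vectors[i] = n_sub * v / l1
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (n_sub - 1)
    cov = (cov + cov.T) / 2.0 + ridge * np.eye(d)
    return KrylovCovariance(matrix=cov, d=d)


def _logdet_pd(matrix: np.ndarray) -> float:
    """log-determinant via Cholesky; raises on non-PD input."""
    try:
        chol = np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "matrix is not positive definite; increase the ridge "
            "regularization"
        ) from exc
    return 2.0 * float(np.log(np.diag(chol)).sum())


def pair_similarity(
    c_g: KrylovCovariance,
    c_h: KrylovCovariance,
    variant: str = "as_printed",
) -> float:
    """Log-determinant similarity of two sub-network descriptors.

    ``as_printed``: exp(-1/2 [log|A| - log|C_G| - log|C_H|]);
    ``s_divergence``: exp(-1/2 [log|A| - (log|C_G| + log|C_H|)/2]),
    with A = (C_G + C_H)/2.  Symmetric and strictly positive in both
    variants; only the second is bounded by 1 with unit self-similarity.
    """
    if variant not in KERNEL_VARIANTS:
        raise ValueError(f"unknown kernel variant {variant!r}")
    if c_g.d != c_h.d:
        raise ValueError("descriptors have different dimensions")
    ld_g = _logdet_pd(c_g.matrix)
    ld_h = _logdet_pd(c_h.matrix)
    ld_a = _logdet_pd((c_g.matrix + c_h.matrix) / 2.0)
    if variant == "as_printed":
        exponent = -0.5 * (ld_a - ld_g - ld_h)
    else:
        exponent = -0.5 * (ld_a - 0.5 * ld_g - 0.5 * ld_h)
    return float(np.exp(exponent))


def _descriptor_stack(
    tree: TreeNetwork,
    h: int,
    d: int,
    ridge: float,
    subgraph_weights: str = "binary",
) -> tuple[np.ndarray, np.ndarray]:
    """All (node, radius) descriptors of a network.

    Returns the stacked covariance matrices, shape (n, h, d, d), and
    their log-determinants, shape (n, h).
    """
    n = tree.n_nodes
    weight_matrix = _tree_weight_matrix(tree, subgraph_weights)
    covs = np.empty((n, h, d, d))
    for i in range(n):
        subs = extract_subnetworks(tree, i, h)
        for j in range(h):
            idx = np.asarray(subs.node_sets[j])
            sub_w = weight_matrix[np.ix_(idx, idx)]
            covs[i, j] = krylov_covariance(sub_w, d, ridge).matrix
    sign, logdet = np.linalg.slogdet(covs)
    if np.any(sign <= 0):
        raise ValueError(
            "non-positive-definite descriptor; increase the ridge "
            "regularization"
        )
    return covs, logdet


def _kernel_from_stacks(
    covs_g: np.ndarray,
    ld_g: np.ndarray,
    covs_h: np.ndarray,
    ld_h: np.ndarray,
    variant: str,
) -> float:
    """Mean pair similarity over all (node, radius) descriptor pairs."""
    sign, ld_a = np.linalg.slogdet((covs_g + covs_h) / 2.0)
    if np.any(sign <= 0):
        raise ValueError("non-positive-definite averaged descriptor")
    if variant == "as_printed":
        exponent = -0.5 * (ld_a - ld_g - ld_h)
    else:
        exponent = -0.5 * (ld_a - 0.5 * ld_g - 0.5 * ld_h)
    return float(np.exp(exponent).mean())


def subnetwork_kernel(
    tree_g: TreeNetwork,
    tree_h: TreeNetwork,
    h: int,
    d: int,
    ridge: float = DEFAULT_RIDGE,
    variant: str = "as_printed",
    subgraph_weights: str = "binary",
) -> float:
    """Sub-network kernel between two networks on the same node set.

    k(G, H) = 1/n sum_i f(G_i^h, H_i^h) with f the mean over radii of the
    per-sub-network similarity g; symmetric and strictly positive.
    """
    if variant not in KERNEL_VARIANTS:
        raise ValueError(f"unknown kernel variant {variant!r}")
    if tree_g.nodes != tree_h.nodes:
        raise ValueError("networks must share node count and node ordering")
    if h < 1 or d < 1:
        raise ValueError("h and d must be >= 1")
    covs_g, ld_g = _descriptor_stack(tree_g, h, d, ridge, subgraph_weights)
    covs_h, ld_h = _descriptor_stack(tree_h, h, d, ridge, subgraph_weights)
    return _kernel_from_stacks(covs_g, ld_g, covs_h, ld_h, variant)


def normalize_similarity(raw: np.ndarray) -> np.ndarray:
    """Cosine-style normalization s(X,Y) / sqrt(s(X,X) s(Y,Y)).

    Maps any raw similarity matrix with strictly positive diagonal to one
    with unit diagonal; a matrix that already has unit diagonal is left
    unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    diag = np.diag(raw)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive self-similarity for subject index(es) {bad.tolist()}"
        )
    scale = np.sqrt(np.outer(diag, diag))
    out = raw / scale
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def structure_similarity_matrix(
    trees: list[TreeNetwork],
    h: int,
    d: int,
    ridge: float = DEFAULT_RIDGE,
    variant: str = "as_printed",
    subgraph_weights: str = "binary",
) -> np.ndarray:
    """Normalized pairwise sub-network-kernel matrix of a cohort.

    Entries lie in (0, 1] with unit diagonal: per sub-network,
    log|A| >= (log|C_G| + log|C_H|)/2 by concavity of the log-determinant,
    so g(G,H) <= sqrt(g(G,G) g(H,H)); Cauchy-Schwarz then bounds the
    normalized kernel by 1.
    """
    if not trees:
        raise ValueError("empty cohort")
    if variant not in KERNEL_VARIANTS:
        raise ValueError(f"unknown kernel variant {variant!r}")
    ref = trees[0].nodes
    for idx, t in enumerate(trees):
        if t.nodes != ref:
            raise ValueError(
                f"network {idx} has a different node set/order than network 0"
            )
    stacks = [
        _descriptor_stack(t, h, d, ridge, subgraph_weights) for t in trees
    ]
    n_subjects = len(trees)
    raw = np.empty((n_subjects, n_subjects))
    for a in range(n_subjects):
        covs_a, ld_a = stacks[a]
        for b in range(a, n_subjects):
            covs_b, ld_b = stacks[b]
            raw[a, b] = raw[b, a] = _kernel_from_stacks(
                covs_a, ld_a, covs_b, ld_b, variant
            )
    out = normalize_similarity(raw)
    return np.clip(out, 0.0, 1.0)
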