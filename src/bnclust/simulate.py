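"""Synthetic cohorts with planted group structure.

Emulates the statistical structure that the clustering pipeline consumes
from real resting-state cohorts: per-subject tree networks (or regional
time series) in which diagnostic groups differ by the placement of a
dominant hub.  Hub relocation is the planted contrast because both
similarity channels are sensitive to it — betweenness concentrates on
hubs, and the sub-network kernel sees their neighborhood structure —
mirroring the association of brain disorders with hub alterations.

Group templates interpolate between a hub at one node (group 0) and a
hub at another (group 1): ``effect`` sets the fraction of hub
attachments relocated, ``noise`` the per-edge rewiring rate applied to
each subject's copy of its template.  Cohorts are fully reproducible
from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import TimeSeriesMatrix, TreeNetwork, default_region_names

logger = logging.getLogger("bnclust")

_MAX_REWIRE_RETRIES = 100


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    effect in [0, 1] is the topological divergence between group
    templates (fraction of relocatable edges moved); noise >= 0 is the
    expected fraction of a subject's edges that are randomly rewired.
    """

    n_nodes: int = 32
    n_per_group: int = 20
    n_groups: int = 2
    effect: float = 0.8
    noise: float = 0.05
    seed: int = 0
    mode: str = "tree"
    region_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if self.noise < 0.0:
            raise ValueError("noise must be >= 0")
        if self.mode not in ("tree", "timeseries"):
            raise ValueError("mode must be 'tree' or 'timeseries'")
        names = self.region_names or tuple(default_region_names(self.n_nodes))
        if len(names) != self.n_nodes:
            raise ValueError("region_names length must equal n_nodes")
        object.__setattr__(self, "region_names", tuple(names))


def _tree_from_parents(
    parents: dict[int, int], names: tuple[str, ...]
) -> TreeNetwork:
    n = len(names)
    edges = frozenset(
        (min(c, p), max(c, p)) for c, p in parents.items()
    )
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    return TreeNetwork(nodes=names, edges=edges, adjacency=adj)


def _group_template(
    spec: CohortSpec, group: int, rng: np.random.Generator
) -> TreeNetwork:
    """Base (group 0) template: a hub-dominated tree anchored at node 0.

    Each node attaches to the hub with probability 0.8, otherwise to a
    random earlier node.  Templates of the other groups are derived from
    this one by :func:`_derive_group_template`, which relocates a
    fraction ``effect`` of the hub attachments to an alternative hub —
    the groups diverge purely in hub placement.
    """
    del group  # base template only; divergence handled downstream
    n = spec.n_nodes
    parents: dict[int, int] = {}
    for v in range(1, n):
        if v == 1 or rng.random() < 0.8:
            parents[v] = 0
        else:
            parents[v] = int(rng.integers(1, v))
    return _tree_from_parents(parents, spec.region_names)


def _rewire_tree(
    tree: TreeNetwork, noise: float, rng: np.random.Generator
) -> TreeNetwork:
    """Random loop-free perturbation of a tree.

    Each rewiring step removes one random edge and reconnects the two
    resulting components with a uniformly random cross edge — the result
    is always a spanning tree, so no retry is normally needed; a bounded
    retry guard protects against degenerate proposals.
    """
    n = tree.n_nodes
    edges = sorted(tree.edges)
    n_rewires = int(rng.binomial(n - 1, min(noise, 1.0))) if noise > 0 else 0
    if n_rewires == 0:
        return tree
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    for _ in range(n_rewires):
        for _attempt in range(_MAX_REWIRE_RETRIES):
            all_edges = sorted(
                (i, j) for i in adj for j in adj[i] if i < j
            )
            u, v = all_edges[rng.integers(len(all_edges))]
            adj[u].discard(v)
            adj[v].discard(u)
            # component containing u after the cut
            comp_u, stack = {u}, [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in comp_u:
                        comp_u.add(y)
                        stack.append(y)
            comp_v = sorted(set(range(n)) - comp_u)
            a = sorted(comp_u)[rng.integers(len(comp_u))]
            b = comp_v[rng.integers(len(comp_v))]
            if (min(a, b), max(a, b)) == (min(u, v), max(u, v)):
                adj[u].add(v)
                adj[v].add(u)
                continue  # identical edge re-added: not a rewire, retry
            adj[a].add(b)
            adj[b].add(a)
            break
        else:
            raise ValueError(
                f"failed to find a valid rewire in {_MAX_REWIRE_RETRIES} tries"
            )
    new_edges = frozenset(
        (i, j) for i in adj for j in adj[i] if i < j
    )
    new_adj = np.zeros((n, n))
    for i, j in new_edges:
        new_adj[i, j] = new_adj[j, i] = 1.0
    return TreeNetwork(nodes=tree.nodes, edges=new_edges, adjacency=new_adj)


def planted_tree_cohort(
    spec: CohortSpec,
) -> tuple[list[TreeNetwork], np.ndarray]:
    """Cohort of tree networks with planted group topology.

    Returns one tree per subject (groups contiguous, ``n_per_group``
    each) and the ground-truth class vector.  With noise = 0 every
    subject equals its group template exactly; with effect = 0 all
    templates coincide and the cohort carries no group signal.
    """
    if spec.mode != "tree":
        raise ValueError("planted_tree_cohort requires mode='tree'")
    rng = np.random.default_rng(spec.seed)
    template_rng = np.random.default_rng(rng.integers(2**31))
    base = _group_template(spec, 0, template_rng)
    templates = [base] + [
        _derive_group_template(spec, g, base)
        for g in range(1, spec.n_groups)
    ]
    trees: list[TreeNetwork] = []
    classes: list[int] = []
    for g, template in enumerate(templates):
        for _ in range(spec.n_per_group):
            trees.append(_rewire_tree(template, spec.noise, rng))
            classes.append(g)
    return trees, np.asarray(classes, dtype=int)


def _derive_group_template(
    spec: CohortSpec, group: int, base: TreeNetwork
) -> TreeNetwork:
    """Relocate round(effect * k) hub attachments of the base template."""
    n = spec.n_nodes
    parents: dict[int, int] = {}
    # recover parent structure of the base tree rooted at node 0
    adj = {i: set() for i in range(n)}
    for i, j in base.edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                parents[y] = x
                stack.append(y)
    alt_hub = max(1, (group * n) // spec.n_groups - 1)
    # nodes on alt_hub's ancestor chain must keep their parent, else the
    # relocation would put an ancestor of alt_hub below it (a cycle)
    ancestors = set()
    x = alt_hub
    while x != 0:
        ancestors.add(x)
        x = parents[x]
    attached = sorted(
        v for v, p in parents.items() if p == 0 and v not in ancestors
    )
    n_move = int(round(spec.effect * len(attached)))
    move_rng = np.random.default_rng(spec.seed + 7919 * group)
    movers = move_rng.choice(attached, size=n_move, replace=False)
    for v in movers:
        parents[int(v)] = alt_hub
    return _tree_from_parents(parents, spec.region_names)


def _nearest_correlation(
    matrix: np.ndarray, floor: float = 1e-6
) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues to make a symmetric matrix PD, rescale to unit diag."""
    sym = (matrix + matrix.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(sym)
    clipped = eigvals < floor
    if clipped.any():
        eigvals = np.maximum(eigvals, floor)
        sym = eigvecs @ np.diag(eigvals) @ eigvecs.T
    scale = np.sqrt(np.diag(sym))
    sym = sym / np.outer(scale, scale)
    np.fill_diagonal(sym, 1.0)
    return sym, bool(clipped.any())


def planted_timeseries_cohort(
    spec: CohortSpec, n_timepoints: int | None = None, edge_strength: float = 0.6
) -> tuple[list[TimeSeriesMatrix], np.ndarray]:
    """Cohort of regional time series with planted correlation structure.

    Each group's target correlation matrix is the identity plus
    s * A(template tree), with s = min(edge_strength, 0.9 / lambda_max(A))
    so the target is positive definite by construction — the strong-edge
    skeleton of the correlation is exactly the group's template tree.
    Per subject, off-diagonal Gaussian jitter of scale ``noise`` is added
    (eigenvalues clipped if the jittered matrix loses definiteness, with
    a logged warning) and T time points are drawn from the zero-mean
    multivariate normal.  Default T = 5 * n_nodes.
    """
    if spec.mode != "timeseries":
        raise ValueError("planted_timeseries_cohort requires mode='timeseries'")
    n = spec.n_nodes
    t_points = n_timepoints if n_timepoints is not None else 5 * n
    if t_points < 5 * n:
        raise ValueError(f"n_timepoints must be >= {5 * n} for {n} regions")
    rng = np.random.default_rng(spec.seed)

    tree_spec = CohortSpec(
        n_nodes=spec.n_nodes,
        n_per_group=spec.n_per_group,
        n_groups=spec.n_groups,
        effect=spec.effect,
        noise=0.0,
        seed=spec.seed,
        mode="tree",
        region_names=spec.region_names,
    )
    templates, _ = planted_tree_cohort(tree_spec)
    group_templates = [
        templates[g * spec.n_per_group] for g in range(spec.n_groups)
    ]

    series: list[TimeSeriesMatrix] = []
    classes: list[int] = []
    for g, template in enumerate(group_templates):
        adj = template.adjacency
        lam_max = float(np.linalg.eigvalsh(adj)[-1])
        s = min(edge_strength, 0.9 / lam_max)
        target = np.eye(n) + s * adj
        for _ in range(spec.n_per_group):
            jitter = rng.normal(scale=spec.noise, size=(n, n))
            jitter = (jitter + jitter.T) / 2.0
            np.fill_diagonal(jitter, 0.0)
            sigma, was_clipped = _nearest_correlation(target + jitter)
            if was_clipped:
                logger.warning(
                    "subject correlation target was not PD; eigenvalues clipped"
                )
            chol = np.linalg.cholesky(sigma)
            data = rng.standard_normal((t_points, n)) @ chol.T
            series.append(
                TimeSeriesMatrix(values=data, region_names=spec.region_names)
            )
            classes.append(g)
    return series, np.asarray(classes, dtype=int)
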