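# Methods

## Pipeline

Given per-subject regional time series (T time points × n regions), the
pipeline is:

1. **Correlation network.** Pairwise Pearson correlation of the region
   time series; diagonal stored as zero. Inputs with fewer than 3 time
   points or any zero-variance region are rejected (the correlation is
   degenerate or undefined). Precomputed connectivity matrices or
   weighted edge lists can be supplied instead.
2. **Spanning tree.** Kruskal's procedure over the off-diagonal weights
   in *descending* order: link the highest-weight pair, skip any link
   that closes a loop, stop at n−1 edges. On correlation weights this
   is formally a maximum-weight spanning tree; the construction keeps
   the strongest-connection backbone and removes the need for a
   binarization threshold. Negative correlations are retained and sort
   last; no absolute-value transform is applied. Equal weights are
   processed in lexicographic (i, j) order so the output is
   deterministic. The output is invariant under any strictly
   increasing transform of the weights.
3. **Attribute similarity.** Normalized node betweenness per network
   (ordered-pair counting over (n−1)(n−2), so a star center scores
   exactly 1 and leaves 0), then cosine similarity between the
   betweenness vectors of each network pair. Betweenness is computed on
   the unweighted tree topology; the shortest-path-count ratio in the
   definition is kept so the operation remains correct on general
   graphs with non-unique shortest paths.
4. **Structure similarity.** The sub-network kernel described below,
   followed by cosine-style normalization to unit diagonal.
5. **Fusion and clustering.** s = δ·s_att + (1−δ)·s_str entry-wise;
   normalized spectral clustering on the fused matrix; optional
   consistency scoring against diagnostic classes.

## Sub-network kernel

For node i and radius j ≤ h, the sub-network is the induced subgraph of
all nodes within hop distance j of i (node sets are nested in j and
saturate at the whole network once j reaches the node's eccentricity).
Sub-network adjacency is binary by default — the networks being
compared are unweighted trees — with an option to carry correlation
weights instead.

Each sub-network with adjacency W and N nodes is summarized by the
sample covariance (denominator N−1) across node positions of the d
vectors u_i = N·W^i e/‖W^i e‖₁, i = 1..d. The scaling by N makes each
normalized power vector average to 1; the power-0 vector e is excluded
since it is constant and contributes zero covariance. The descriptor is
ridge-regularized (default ridge = 1e−6·I) because small or regular
sub-networks give exactly singular covariances — for any k-regular
sub-network every u_i is constant and the descriptor is exactly
ridge·I. Log-determinants are always taken through a Cholesky
factorization; a factorization failure is reported as non-positive-
definiteness with the advice to increase the ridge.

Two variants of the per-sub-network similarity are provided:

- `as_printed` (default): g = exp(−½[log|A| − log|C_G| − log|C_H|]).
  Self-similarity is |C|^(1/2), so the cohort matrix is normalized by
  s(X,Y)/√(s(X,X)s(Y,Y)) afterwards. The normalized matrix provably
  lies in (0, 1]: log-det concavity gives
  log|A| ≥ (log|C_G|+log|C_H|)/2, hence g(G,H) ≤ √(g(G,G)·g(H,H))
  per sub-network, and Cauchy–Schwarz carries the bound through the
  averaging over nodes and radii.
- `s_divergence`: g = exp(−½[log|A| − ½log|C_G| − ½log|C_H|]), the
  symmetric Stein/log-det divergence kernel, bounded by 1 with unit
  self-similarity. The two differ only in whether the denominator
  determinants carry square roots; after normalization they agree
  whenever self-similarities are homogeneous across the cohort, and in
  practice they produce nearly identical similarity matrices. Both are
  exposed so either convention can be reproduced exactly.

No claim of positive semi-definiteness is made for either variant as a
kernel matrix; the values are used as similarity scores only.

## Spectral clustering and consistency

D is the diagonal of row sums of the fused similarity matrix S (always
strictly positive, since the diagonal of S is 1). The embedding is the
m leading eigenvectors of D^(−1/2) S D^(−1/2), eigenvalues sorted
descending, each eigenvector's sign fixed so its first component above
1e−12 in magnitude is positive; rows are renormalized to unit length
(all-zero rows are left unnormalized and logged). k-means uses
k-means++ greedy seeding, 50 restarts, relative tolerance 1e−6, at most
300 iterations, and a caller-supplied seed, so labels are reproducible
run to run. The number of clusters defaults to 2 (patients vs
controls).

Consistency is the maximum, over one-to-one cluster↔class assignments,
of the total matched count divided by cohort size, computed by optimal
linear assignment on the confusion matrix; for m = 2 it reduces to
max(T11+T22, T12+T21)/n. It is invariant to relabeling of clusters or
classes.

The (δ, h, d) grid sweep scores consistency, which requires the
diagnostic labels — it is therefore a *supervised evaluation* mode for
characterizing parameter sensitivity, not unsupervised discovery; the
single-setting run is the primary mode. Default grids: δ ∈ {0.1..0.9}
step 0.1, h ∈ {1, 2, 3}, d ∈ {3..8}.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| δ | weight of attribute vs structure similarity | 0.5 | 1 = attribute only, 0 = kernel only |
| h | maximum sub-network radius (hops) | 2 | the dominant sensitivity parameter |
| d | power iterations in the descriptor | 3 | results are robust to d |
| ridge | diagonal regularization of descriptors | 1e−6 | dimensionless; must be > 0 in practice |
| m | number of clusters | 2 | patient/control contrast |
| seed | k-means / generator seed | 0 | fixes all randomness |

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes,
not fMRI physics (no hemodynamics, motion, or acquisition noise).
Group templates are hub-position contrasts: the base template is a
hub-dominated random tree (each node attaches to the hub node with
probability 0.8, otherwise to a random earlier node); other groups
relocate round(effect·k) of the k hub attachments to an alternative hub
node. Hub contrasts were chosen because both similarity channels —
betweenness and the sub-network kernel — are sensitive to hub
placement, matching the association of brain disorders with hub
alterations. Subjects are sampled from their template by per-edge
rewiring at rate `noise`: cut a random edge and reconnect the two
components with a random cross edge, which always yields a valid tree.
Defaults (32 nodes, 20 subjects per group, effect 0.8, noise 0.05)
mirror a typical single-site cohort scale on a 32-region parcellation.

Time-series mode: each group's target correlation is I + s·A(template)
with s = min(0.6, 0.9/λ_max(A)), positive definite by construction;
per-subject off-diagonal Gaussian jitter of scale `noise` is added,
eigenvalues are clipped at 1e−6 if definiteness is lost (logged), the
matrix is rescaled to unit diagonal, and T ≥ 5n time points are drawn
from the zero-mean multivariate normal. Sample correlations of
generated subjects recover the template's edge skeleton as T grows.

Because the planted contrast is exactly the kind of signal both
channels detect, passing end-to-end tests demonstrates that the
pipeline recovers strong topological group structure under mild noise —
not that it would attain any particular accuracy on real clinical
cohorts, where effect sizes are far smaller and the parcellation,
preprocessing and scanner noise all matter.

## Numerical and design choices

- Delimited-text output uses 12 significant digits; all readers/writers
  round-trip at that precision. Subject IDs are file stems; files are
  read in lexicographic filename order.
- Weighted-matrix inputs: an exactly-zero off-diagonal entry counts as
  an absent edge for connectivity checking and edge sorting.
- Edge-list inputs order nodes by sorted label, so subjects sharing a
  label set are aligned regardless of edge order on disk; cohorts
  mixing headered and headerless matrix files fall back to positional
  alignment with a logged warning.
- Test and verification problem sizes (trees of n ≤ 12 against
  exhaustive oracles, cohorts of 40 subjects at 32 nodes for end-to-end
  checks) were chosen so the full suite exercises every stage, at exact
  oracle tolerances of 1e−10 to 1e−12, within seconds.

## Known limitations

- The pipeline starts from regional time series or connectivity
  matrices; fMRI preprocessing (registration, nuisance regression,
  filtering, parcellation) must be done upstream.
- The tree reduction discards all cycle structure and edge weights;
  group differences expressed only in weak or redundant connections are
  invisible to it.
- The as-printed kernel variant is not a proper Mercer kernel; spectral
  clustering treats the fused matrix as a similarity graph, which is
  well-defined regardless.
- The grid sweep's consistency objective uses diagnostic labels, so
  parameters selected by sweeping cannot be reported as unsupervised
  performance.
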