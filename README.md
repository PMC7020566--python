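# bnclust

Unsupervised clustering of subjects by the similarity of their brain
functional connectivity networks — for researchers who have per-subject
resting-state regional time series (or precomputed connectivity
matrices) and want to ask whether network topology alone separates
patient groups from controls, without using any clinical labels.

## Method

For each subject, regional time series are correlated (Pearson) into a
fully connected network, which is reduced to its spanning tree by
Kruskal's procedure in descending weight order — the loopless backbone
linking all regions through their strongest connections, avoiding the
arbitrary threshold of binarized networks. Two complementary
similarities are then computed between every pair of subject networks
*G*, *H* on the same parcellation:

- **Attribute similarity** — cosine similarity of the networks'
  normalized node-betweenness vectors,
  *s*<sub>att</sub>(G,H) = Σ b<sub>m</sub>(G) b<sub>m</sub>(H) /
  (‖b(G)‖ ‖b(H)‖), where
  b<sub>i</sub> = 1/((n−1)(n−2)) Σ<sub>h≠j≠i</sub> ρ<sub>hj</sub><sup>i</sup>/ρ<sub>hj</sub>
  is the fraction of shortest paths between other node pairs passing
  through node *i*. This channel is sensitive to hub placement.

- **Structure similarity** — a sub-network kernel: around every node,
  nested induced subgraphs of hop radius *j* = 1..*h* are extracted;
  each is summarized by the d×d covariance of its Krylov power-iteration
  vectors u<sub>i</sub> = N W<sup>i</sup>e/‖W<sup>i</sup>e‖₁ (W the
  sub-network adjacency, e the all-ones vector); same-node, same-radius
  descriptors are compared through the log-determinant similarity
  g = exp(−½[log|A| − log|C<sub>G</sub>| − log|C<sub>H</sub>|]),
  A = (C<sub>G</sub>+C<sub>H</sub>)/2, and the kernel
  k(G,H) = 1/n Σ<sub>i</sub> 1/h Σ<sub>j</sub> g averages over all nodes
  and radii. The cohort kernel matrix is normalized to unit diagonal by
  s(X,Y)/√(s(X,X)s(Y,Y)).

The two channels are fused by a convex weight δ,
s = δ s<sub>att</sub> + (1−δ) s<sub>str</sub>, and subjects are
clustered by normalized spectral clustering (top-*m* eigenvectors of
D<sup>−1/2</sup>SD<sup>−1/2</sup>, row-normalized, k-means). Agreement
with diagnostic classes, when available, is scored by **clustering
consistency**: the best one-to-one matching of clusters to classes,
divided by cohort size.

A synthetic-cohort generator plants group-specific hub positions in
tree networks (or block-correlated time series), so the whole pipeline
is testable without any imaging data.

## Worked example

Simulate a two-group cohort of 40 tree networks (32 regions, 20
subjects per group, strong hub contrast, 5% edge noise) and cluster it:

```bash
bnclust simulate --output demo --mode tree --seed 7
bnclust cluster --input-dir demo/subjects --input-kind edgelist \
    --labels demo/classes.tsv --output demo/run \
    --delta 0.5 --h 2 --d 3 --seed 1
```

which prints

```
wrote 40 subjects (edgelist) under demo/subjects
class labels: demo/classes.tsv
clustered 40 subjects into 2 groups
consistency vs supplied classes: 1.0000
  labels: demo/run/cluster_labels.tsv
  attribute: demo/run/similarity_attribute.tsv
  structure: demo/run/similarity_structure.tsv
  fused: demo/run/similarity_fused.tsv
  manifest: demo/run/run_manifest.txt
```

Consistency 1.0000 means the two recovered clusters coincide exactly
with the planted groups under the best cluster-to-group matching. The
output directory holds per-subject cluster labels, the attribute,
structure and fused similarity matrices (tab-delimited, subject IDs as
header), and a manifest of all parameters sufficient to re-run the
clustering identically. `bnclust sweep` evaluates a (δ, h, d) grid
against supplied diagnostic labels — a supervised evaluation mode, kept
separate from the unsupervised single-setting run.

The same pipeline runs from Python:

```python
from bnclust import CohortSpec, planted_tree_cohort, cluster_cohort

trees, classes = planted_tree_cohort(CohortSpec(seed=7))
result, matrices = cluster_cohort(trees, delta=0.5, h=2, d=3,
                                  classes=classes, seed=1)
print(result.consistency)   # 1.0
```

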