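"""Hierarchical clustering on correlation distance, consensus clustering and
silhouette validation.

Samples are compared with the distance 1 - Pearson correlation of their
expression profiles, clustered by agglomerative average linkage (UPGMA), and
the stability of a k-group partition is quantified by consensus clustering:
repeated clustering on random feature subsets (default 80% of features,
without replacement, all samples retained) and accumulation of co-assignment
frequencies.  Per-sample silhouette widths flag samples that do not fit their
assigned cluster (negative width -> "undetermined").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "pearson_distance",
    "hier_cluster",
    "cut_clusters",
    "consensus_cluster",
    "silhouette_widths",
    "ConsensusResult",
    "SilhouetteResult",
    "dendrogram_to_newick",
]


def pearson_distance(m: pd.DataFrame) -> pd.DataFrame:
    """Distance matrix d(i,j) = 1 - Pearson r between sample profiles.

    ``m`` is features x samples; entries lie in [0, 2].
    """
    if m.shape[0] < 2:
        raise ValueError("need >= 2 features to correlate sample profiles")
    values = m.to_numpy(float)
    sds = values.std(axis=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(
            f"constant sample profile(s): {', '.join(m.columns[zero])}"
        )
    d = 1.0 - np.corrcoef(values, rowvar=False)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


def hier_cluster(d: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) from a distance matrix."""
    if d.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    condensed = squareform(d.to_numpy(float), checks=False)
    return linkage(condensed, method=method)


def cut_clusters(z: np.ndarray, k: int) -> np.ndarray:
    """Cut a merge tree into exactly k groups by undoing the k-1 highest merges.

    Returns integer labels 1..k, numbered by first sample occurrence.
    """
    n = z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - k):  # apply all but the k-1 highest merges
        a, b = int(z[i, 0]), int(z[i, 1])
        parent[find(a)] = n + i
        parent[find(b)] = n + i
    roots: dict[int, int] = {}
    labels = np.empty(n, int)
    for s in range(n):
        r = find(s)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[s] = roots[r]
    return labels


@dataclass
class ConsensusResult:
    """Co-clustering frequencies and the derived stable partition."""

    consensus: pd.DataFrame  # samples x samples, in [0, 1]
    labels: pd.Series  # final partition: HC on 1-consensus, cut at k
    k: int
    iterations: int
    feature_fraction: float
    seed: int

    def validate(self) -> None:
        c = self.consensus.to_numpy()
        assert np.allclose(c, c.T), "consensus matrix must be symmetric"
        assert np.allclose(np.diag(c), 1.0), "consensus diagonal must be 1"
        assert c.min() >= 0 and c.max() <= 1, "consensus entries must be in [0,1]"


def consensus_cluster(
    m: pd.DataFrame,
    k: int,
    iterations: int = 1000,
    feature_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering by feature subsampling.

    Each iteration draws ceil(feature_fraction * F) features without
    replacement, clusters all samples on them (1-Pearson, average linkage,
    cut at k) and records co-assignments; the final partition is average-
    linkage clustering of 1-consensus cut at the same k.
    """
    if m.shape[0] < 10:
        raise ValueError("need >= 10 features for consensus clustering")
    if not 0 < feature_fraction <= 1:
        raise ValueError("feature_fraction must be in (0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n_feat = int(np.ceil(feature_fraction * m.shape[0]))
    n = m.shape[1]
    co = np.zeros((n, n))
    for _ in range(iterations):
        idx = rng.choice(m.shape[0], n_feat, replace=False)
        sub = m.iloc[idx]
        labels = cut_clusters(hier_cluster(pearson_distance(sub)), k)
        co += labels[:, None] == labels[None, :]
    consensus = pd.DataFrame(co / iterations, index=m.columns, columns=m.columns)
    dist = 1.0 - consensus.to_numpy()
    np.fill_diagonal(dist, 0.0)
    final = cut_clusters(
        linkage(squareform(dist, checks=False), method="average"), k
    )
    result = ConsensusResult(
        consensus=consensus,
        labels=pd.Series(final, index=m.columns, name="consensus_cluster"),
        k=k,
        iterations=iterations,
        feature_fraction=feature_fraction,
        seed=seed,
    )
    result.validate()
    return result


@dataclass
class SilhouetteResult:
    """Per-sample silhouette widths with cluster and overall summaries."""

    widths: pd.Series  # s(i) in [-1, 1]
    cluster_means: dict
    overall_mean: float

    @property
    def undetermined(self) -> pd.Index:
        """Samples with negative width (misassigned / undetermined)."""
        return self.widths.index[self.widths < 0]


def silhouette_widths(d: pd.DataFrame, labels) -> SilhouetteResult:
    """Rousseeuw silhouette widths from a precomputed distance matrix.

    s(i) = (b - a) / max(a, b) with a = mean distance to the sample's own
    cluster and b = the smallest mean distance to another cluster; members of
    singleton clusters get s = 0 by convention.
    """
    labels = np.asarray(pd.Series(labels, index=d.index).loc[d.index])
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    dist = d.to_numpy(float)
    n = dist.shape[0]
    masks = {c: labels == c for c in uniq}
    sizes = {c: masks[c].sum() for c in uniq}
    mean_to = {c: dist[:, masks[c]].sum(axis=1) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton convention: s = 0
        a = mean_to[c][i] / (sizes[c] - 1)
        b = min(mean_to[o][i] / sizes[o] for o in uniq if o != c)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    widths = pd.Series(s, index=d.index, name="silhouette")
    return SilhouetteResult(
        widths=widths,
        cluster_means={c: float(widths[masks[c]].mean()) for c in uniq},
        overall_mean=float(widths.mean()),
    )


def dendrogram_to_newick(z: np.ndarray, leaf_names) -> str:
    """Render a scipy merge tree as Newick text with merge heights as lengths."""
    tree = to_tree(z)
    names = list(leaf_names)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
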