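"""Cross-dataset subtype correspondence (simplified subclass mapping).

For clusters a (dataset A) and b (dataset B): the markers of a are the top
``n_marker`` genes by a-vs-rest pooled t-statistic in A; their enrichment near
the top of B's b-vs-rest t-ranking is measured by the mean rank of the
markers, with significance from permuting B's sample labels (add-one
estimator, floor 1/(n_perm+1)).  The test is run in both directions and the
pairwise p-value is the max of the two; Benjamini-Hochberg FDR is applied
across all k_A x k_B pairs.  This is a functional analog of subclass mapping
(correspondence + FDR semantics), not a numerical clone of the GSEA-based
original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrespondenceResult", "subtype_correspondence"]


@dataclass
class CorrespondenceResult:
    """Pairwise correspondence FDRs with the underlying directional p-values."""

    fdr: pd.DataFrame  # clusters_A x clusters_B
    p: pd.DataFrame  # max of the two directions
    p_a_to_b: pd.DataFrame
    p_b_to_a: pd.DataFrame
    n_marker: int
    n_perm: int
    seed: int


def _tstats(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per gene, group-in-mask vs rest."""
    n1, n0 = mask.sum(), (~mask).sum()
    x1, x0 = X[:, mask], X[:, ~mask]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    sp2 = ss / (n1 + n0 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    denom[denom == 0] = np.finfo(float).tiny
    return (m1 - m0) / denom


def _marker_sets(
    X: np.ndarray, genes: pd.Index, labels: np.ndarray, clusters, n_marker: int
) -> dict:
    markers = {}
    for c in clusters:
        t = _tstats(X, labels == c)
        top = np.argsort(-t, kind="stable")[:n_marker]
        markers[c] = genes[top]
    return markers


def _direction_pvalues(
    source_markers: dict,
    target_X: np.ndarray,
    target_genes: pd.Index,
    target_labels: np.ndarray,
    target_clusters,
    n_perm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """p[a, b]: enrichment of a's markers at the top of b-vs-rest in target."""
    gene_pos = {g: i for i, g in enumerate(target_genes)}
    marker_idx = {a: np.array([gene_pos[g] for g in gl]) for a, gl in source_markers.items()}

    def stats_for(labels: np.ndarray) -> dict:
        out = {}
        for b in target_clusters:
            ranks = rankdata(_tstats(target_X, labels == b))
            out[b] = {a: ranks[idx].mean() for a, idx in marker_idx.items()}
        return out

    observed = stats_for(target_labels)
    exceed = {b: {a: 0 for a in source_markers} for b in target_clusters}
    for _ in range(n_perm):
        perm = rng.permutation(target_labels)
        null = stats_for(perm)
        for b in target_clusters:
            for a in source_markers:
                if null[b][a] >= observed[b][a]:
                    exceed[b][a] += 1
    p = pd.DataFrame(
        index=list(source_markers), columns=list(target_clusters), dtype=float
    )
    for b in target_clusters:
        for a in source_markers:
            p.loc[a, b] = (1 + exceed[b][a]) / (n_perm + 1)
    return p


def subtype_correspondence(
    a_matrix: pd.DataFrame,
    a_labels: pd.Series,
    b_matrix: pd.DataFrame,
    b_labels: pd.Series,
    n_marker: int = 50,
    n_perm: int = 500,
    seed: int = 0,
    direction_seeds: tuple[int, int] | None = None,
) -> CorrespondenceResult:
    """Test which clusters of two datasets correspond.

    ``direction_seeds`` optionally fixes the permutation seeds of the
    A-to-B and B-to-A directions separately (defaults derive from ``seed``).
    """
    shared = a_matrix.index.intersection(b_matrix.index)
    if len(shared) == 0:
        raise ValueError("disjoint gene universes")
    if len(shared) < 2 * n_marker:
        raise ValueError(
            f"shared gene universe ({len(shared)}) must be >= 2 x n_marker"
        )
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a p-value floor of 1/{n_perm + 1}; "
            "results have coarse resolution",
            RuntimeWarning,
            stacklevel=2,
        )
    a_labels = pd.Series(a_labels).loc[a_matrix.columns].astype(str)
    b_labels = pd.Series(b_labels).loc[b_matrix.columns].astype(str)
    for name, lab in (("A", a_labels), ("B", b_labels)):
        small = lab.value_counts()
        small = sorted(small.index[small < 3])
        if small:
            raise ValueError(f"cluster(s) in {name} with < 3 samples: {small}")

    XA = a_matrix.loc[shared].to_numpy(float)
    XB = b_matrix.loc[shared].to_numpy(float)
    la, lb = a_labels.to_numpy(), b_labels.to_numpy()
    clusters_a, clusters_b = sorted(set(la)), sorted(set(lb))

    s1, s2 = direction_seeds if direction_seeds is not None else (seed, seed + 1)
    markers_a = _marker_sets(XA, shared, la, clusters_a, n_marker)
    markers_b = _marker_sets(XB, shared, lb, clusters_b, n_marker)

    p_ab = _direction_pvalues(
        markers_a, XB, shared, lb, clusters_b, n_perm, np.random.default_rng(s1)
    )  # rows a, cols b
    p_ba = _direction_pvalues(
        markers_b, XA, shared, la, clusters_a, n_perm, np.random.default_rng(s2)
    ).T  # transpose to rows a, cols b

    p = pd.DataFrame(
        np.maximum(p_ab.to_numpy(float), p_ba.to_numpy(float)),
        index=clusters_a,
        columns=clusters_b,
    )
    flat = p.to_numpy().ravel()
    fdr = multipletests(flat, method="fdr_bh")[1].reshape(p.shape)
    return CorrespondenceResult(
        fdr=pd.DataFrame(fdr, index=clusters_a, columns=clusters_b),
        p=p,
        p_a_to_b=p_ab,
        p_b_to_a=p_ba,
        n_marker=n_marker,
        n_perm=n_perm,
        seed=seed,
    )
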