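"""Nearest-centroid signature selection and classification (ClaNC-style).

For each gene g and class k a standardized class-vs-overall statistic

    d_kg = (mean_kg - mean_g) / (m_k * (s_g + s0)),   m_k = sqrt(1/n_k + 1/n)

is computed, where s_g is the pooled within-class standard deviation and s0
(the variance-stabilization constant) is the median of the s_g.  Genes are
assigned to classes by iterated global argmax over |d|: the largest remaining
(gene, class) statistic wins, each gene is used at most once, and each class
receives at most ``genes_per_class`` genes, so the active sets are disjoint.

A sample is classified to the class minimizing the standardized squared
distance over the union of active genes, where class k contributes its own
centroid on its active genes and the overall centroid elsewhere.  The
signature size is chosen by stratified five-fold cross-validation: the size
with the lowest error, ties resolved toward fewer genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CentroidSignature",
    "CvReport",
    "clanc_fit",
    "clanc_classify",
    "cv_select_size",
]


@dataclass
class CentroidSignature:
    """Selected genes, centroids and scale parameters of a fitted classifier."""

    classes: list[str]
    active_sets: dict[str, list[str]]
    genes: list[str]  # union of active sets, in selection order
    class_centroids: pd.DataFrame  # genes x classes
    overall_centroid: pd.Series
    pooled_sd: pd.Series
    s0: float
    class_counts: dict[str, int]
    genes_per_class: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.classes:
            dup = seen & set(self.active_sets[c])
            if dup:
                raise ValueError(f"active sets overlap: {sorted(dup)}")
            seen |= set(self.active_sets[c])
        if (self.pooled_sd.loc[self.genes] + self.s0 <= 0).any():
            raise ValueError("non-positive stabilized scale for active genes")


def _class_stats(m: pd.DataFrame, labels: pd.Series):
    labels = pd.Series(labels).loc[m.columns].astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    small = [c for c, v in counts.items() if v < 2]
    if small:
        raise ValueError(f"class(es) with < 2 samples: {', '.join(small)}")
    X = m.to_numpy(float)
    n = X.shape[1]
    overall = X.mean(axis=1)
    class_means = np.stack([X[:, (labels == c).to_numpy()].mean(axis=1) for c in classes])
    ss_within = np.zeros(X.shape[0])
    for i, c in enumerate(classes):
        sub = X[:, (labels == c).to_numpy()]
        ss_within += ((sub - class_means[i][:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss_within / (n - len(classes)))
    return labels, classes, counts, overall, class_means, pooled_sd


def clanc_stats(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """The |d|-statistic matrix (genes x classes) used for gene selection."""
    _, classes, counts, overall, class_means, pooled_sd = _class_stats(m, labels)
    n = sum(counts.values())
    s0 = float(np.median(pooled_sd))
    d = np.empty((m.shape[0], len(classes)))
    for i, c in enumerate(classes):
        mk = np.sqrt(1.0 / counts[c] + 1.0 / n)
        d[:, i] = (class_means[i] - overall) / (mk * (pooled_sd + s0))
    return pd.DataFrame(d, index=m.index, columns=classes)


def _greedy_select(
    absd: pd.DataFrame, genes_per_class: int
) -> dict[str, list[str]]:
    classes = list(absd.columns)
    flat = absd.stack()
    order = flat.sort_values(ascending=False, kind="stable").index
    active: dict[str, list[str]] = {c: [] for c in classes}
    used: set[str] = set()
    filled = 0
    want = genes_per_class * len(classes)
    for gene, cls in order:
        if gene in used or len(active[cls]) >= genes_per_class:
            continue
        active[cls].append(gene)
        used.add(gene)
        filled += 1
        if filled == want:
            break
    return active


def clanc_fit(
    m: pd.DataFrame, labels: pd.Series, genes_per_class: int
) -> CentroidSignature:
    """Fit a centroid signature with ``genes_per_class`` active genes per class."""
    if genes_per_class < 1:
        raise ValueError("genes_per_class must be >= 1")
    labels, classes, counts, overall, class_means, pooled_sd = _class_stats(m, labels)
    if genes_per_class * len(classes) > m.shape[0]:
        raise ValueError(
            f"genes_per_class={genes_per_class} x {len(classes)} classes "
            f"exceeds the {m.shape[0]}-gene pool"
        )
    n = sum(counts.values())
    s0 = float(np.median(pooled_sd))
    d = np.empty((m.shape[0], len(classes)))
    for i, c in enumerate(classes):
        mk = np.sqrt(1.0 / counts[c] + 1.0 / n)
        d[:, i] = (class_means[i] - overall) / (mk * (pooled_sd + s0))
    absd = pd.DataFrame(np.abs(d), index=m.index, columns=classes)
    active = _greedy_select(absd, genes_per_class)
    union = [g for c in classes for g in active[c]]
    centroids = pd.DataFrame(
        class_means.T, index=m.index, columns=classes
    ).loc[union]
    return CentroidSignature(
        classes=classes,
        active_sets=active,
        genes=union,
        class_centroids=centroids,
        overall_centroid=pd.Series(overall, index=m.index).loc[union],
        pooled_sd=pd.Series(pooled_sd, index=m.index).loc[union],
        s0=s0,
        class_counts=counts,
        genes_per_class=genes_per_class,
    )


def clanc_classify(sig: CentroidSignature, profiles: pd.DataFrame) -> pd.DataFrame:
    """Classify sample profiles (genes x samples) by nearest signature centroid.

    Returns a frame with per-class squared-distance scores, the winning label
    and a tie flag.  Ties are broken toward the class with more training
    samples, then label order.
    """
    if isinstance(profiles, pd.Series):
        profiles = profiles.to_frame()
    missing = sorted(set(sig.genes) - set(profiles.index))
    if missing:
        raise ValueError(f"missing signature gene(s): {', '.join(missing)}")
    X = profiles.loc[sig.genes].to_numpy(float)  # union genes x samples
    scale = (sig.pooled_sd.to_numpy() + sig.s0)[:, None]
    scores = np.empty((len(sig.classes), X.shape[1]))
    overall = sig.overall_centroid.to_numpy()[:, None]
    for i, c in enumerate(sig.classes):
        centroid = overall.copy()
        active_mask = np.isin(sig.genes, sig.active_sets[c])
        centroid[active_mask] = sig.class_centroids[c].to_numpy()[active_mask, None]
        scores[i] = (((X - centroid) / scale) ** 2).sum(axis=0)
    out = pd.DataFrame(scores.T, index=profiles.columns, columns=sig.classes)
    labels, ties = [], []
    for _, row in out.iterrows():
        best = row.min()
        cand = [c for c in sig.classes if np.isclose(row[c], best, rtol=0, atol=1e-12)]
        cand.sort(key=lambda c: (-sig.class_counts[c], c))
        labels.append(cand[0])
        ties.append(len(cand) > 1)
    out["label"] = labels
    out["tie"] = ties
    return out


@dataclass
class CvReport:
    """Cross-validated error per candidate signature size."""

    grid: list[int]
    errors: list[float]
    chosen: int
    folds: int
    seed: int
    fold_assignments: pd.Series = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genes_per_class": self.grid, "cv_error": self.errors})


def cv_select_size(
    m: pd.DataFrame,
    labels: pd.Series,
    grid: Sequence[int] = range(1, 201),
    folds: int = 5,
    seed: int = 0,
) -> CvReport:
    """Choose the signature size by stratified k-fold cross-validation.

    The chosen size attains the minimal mean held-out error; among ties the
    smallest size wins (fewest genes at the lowest error rate).
    """
    labels = pd.Series(labels).loc[m.columns].astype(str)
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < folds).any():
        small = sorted(counts.index[counts < folds])
        raise ValueError(f"class(es) smaller than fold count: {', '.join(small)}")
    grid = sorted(set(int(g) for g in grid))
    grid = [g for g in grid if g >= 1 and g * len(classes) <= m.shape[0]]
    if not grid:
        raise ValueError("empty size grid after capping at the gene pool")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = pd.Series(index=m.columns, dtype=int)
    errors = np.zeros(len(grid))
    samples = np.asarray(m.columns)
    for fold, (train_idx, test_idx) in enumerate(skf.split(samples, labels)):
        fold_of.iloc[test_idx] = fold
        train_cols = samples[train_idx]
        test_cols = samples[test_idx]
        absd = clanc_stats(m[train_cols], labels.loc[train_cols]).abs()
        for gi, size in enumerate(grid):
            active = _greedy_select(absd, size)
            sig = _signature_from_stats(
                m[train_cols], labels.loc[train_cols], active, size
            )
            pred = clanc_classify(sig, m[test_cols])["label"]
            errors[gi] += (pred.to_numpy() != labels.loc[test_cols].to_numpy()).mean()
    errors /= folds
    chosen = grid[int(np.argmin(errors))]  # argmin returns the first (smallest) size
    return CvReport(
        grid=grid,
        errors=[float(e) for e in errors],
        chosen=chosen,
        folds=folds,
        seed=seed,
        fold_assignments=fold_of,
    )


def _signature_from_stats(
    m: pd.DataFrame,
    labels: pd.Series,
    active: dict[str, list[str]],
    genes_per_class: int,
) -> CentroidSignature:
    labels, classes, counts, overall, class_means, pooled_sd = _class_stats(m, labels)
    union = [g for c in classes for g in active[c]]
    centroids = pd.DataFrame(class_means.T, index=m.index, columns=classes).loc[union]
    return CentroidSignature(
        classes=classes,
        active_sets=active,
        genes=union,
        class_centroids=centroids,
        overall_centroid=pd.Series(overall, index=m.index).loc[union],
        pooled_sd=pd.Series(pooled_sd, index=m.index).loc[union],
        s0=float(np.median(pooled_sd)),
        class_counts=counts,
        genes_per_class=genes_per_class,
    )
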