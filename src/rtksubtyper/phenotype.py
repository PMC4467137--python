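"""Invasive/proliferative phenotype calls and integration with RTK clusters.

A sample is compared by Pearson correlation with the invasive and the
proliferative centroid of a phenotype signature; with cutoff c (default 0.4)
the call is

* Invasive      if r_inv >= c and r_inv - r_prol >= c,
* Proliferative if r_prol >= c and r_prol - r_inv >= c,
* Undetermined  otherwise,

a partition of the (r_inv, r_prol) plane.  RTK cluster names are decided by
the mean EGFR-minus-ERBB3 contrast between clusters rather than by arbitrary
cluster indices.  RTK and phenotype calls combine into three integrated
subtypes; any undetermined input leaves the sample unassigned, and the
combination EGFR-high/ERBB3-low with a proliferative phenotype (not observed
in melanoma cohorts) is flagged Discordant rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RTK_HIGH",
    "RTK_LOW",
    "INTEGRATED_NAMES",
    "PhenotypeCentroids",
    "build_centroids",
    "phenotype_correlations",
    "classify_phenotype",
    "call_phenotypes",
    "name_rtk_clusters",
    "integrate_subtypes",
]

RTK_HIGH = "EGFR_HIGH_ERBB3_LOW"
RTK_LOW = "EGFR_LOW_ERBB3_HIGH"
UNDETERMINED = "Undetermined"

INTEGRATED_NAMES = {
    "S1": "EGFR_HIGH_ERBB3_LOW-Invasive",
    "S2": "EGFR_LOW_ERBB3_HIGH-Invasive",
    "S3": "EGFR_LOW_ERBB3_HIGH-Proliferative",
}


@dataclass
class PhenotypeCentroids:
    """Mean log2 profiles of the two phenotypes on a shared gene list."""

    genes: list[str]
    invasive: np.ndarray
    proliferative: np.ndarray

    def __post_init__(self) -> None:
        if len(self.invasive) != len(self.genes) or len(self.proliferative) != len(
            self.genes
        ):
            raise ValueError("centroids must be defined on the shared gene list")


def build_centroids(
    m: pd.DataFrame,
    phenotype_labels: pd.Series,
    signature_genes: Sequence[str],
) -> PhenotypeCentroids:
    """Per-gene mean profiles of labeled Invasive / Proliferative samples."""
    genes = list(signature_genes)
    missing = sorted(set(genes) - set(m.index))
    if missing:
        raise ValueError(f"signature gene(s) missing from matrix: {', '.join(missing)}")
    labels = pd.Series(phenotype_labels)
    for phen in ("Invasive", "Proliferative"):
        if (labels == phen).sum() < 2:
            raise ValueError(f"need >= 2 samples labeled {phen}")
    inv_samples = labels.index[labels == "Invasive"]
    pro_samples = labels.index[labels == "Proliferative"]
    if len(set(inv_samples) & set(pro_samples)):
        raise ValueError("overlapping Invasive/Proliferative label sets")
    sub = m.loc[genes]
    return PhenotypeCentroids(
        genes=genes,
        invasive=sub[inv_samples].mean(axis=1).to_numpy(),
        proliferative=sub[pro_samples].mean(axis=1).to_numpy(),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0:
        raise ValueError("constant profile over signature genes")
    return float(np.corrcoef(x, y)[0, 1])


def phenotype_correlations(
    sample_profile: pd.Series, centroids: PhenotypeCentroids
) -> tuple[float, float]:
    """Pearson correlations of a sample with the two phenotype centroids."""
    x = pd.Series(sample_profile).loc[centroids.genes].to_numpy(float)
    return _pearson(x, centroids.invasive), _pearson(x, centroids.proliferative)


def classify_phenotype(r_inv: float, r_prol: float, cutoff: float = 0.4) -> str:
    """Apply the correlation rule at the given cutoff (default 0.4)."""
    if not (-1 - 1e-12 <= r_inv <= 1 + 1e-12 and -1 - 1e-12 <= r_prol <= 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    if r_inv >= cutoff and r_inv - r_prol >= cutoff:
        return "Invasive"
    if r_prol >= cutoff and r_prol - r_inv >= cutoff:
        return "Proliferative"
    return UNDETERMINED


def call_phenotypes(
    m: pd.DataFrame, centroids: PhenotypeCentroids, cutoff: float = 0.4
) -> pd.DataFrame:
    """Phenotype calls for every sample; columns r_inv, r_prol, phenotype."""
    rows = []
    for sample in m.columns:
        r_inv, r_prol = phenotype_correlations(m[sample], centroids)
        rows.append((r_inv, r_prol, classify_phenotype(r_inv, r_prol, cutoff)))
    return pd.DataFrame(rows, index=m.columns, columns=["r_inv", "r_prol", "phenotype"])


def name_rtk_clusters(
    m: pd.DataFrame,
    cluster_labels: pd.Series,
    egfr_genes: Sequence[str] = ("EGFR",),
    erbb3_genes: Sequence[str] = ("ERBB3",),
) -> dict:
    """Map the two RTK cluster indices to named labels.

    The cluster with the larger mean EGFR-minus-ERBB3 contrast becomes
    EGFR_HIGH_ERBB3_LOW, the other EGFR_LOW_ERBB3_HIGH.
    """
    labels = pd.Series(cluster_labels).loc[m.columns]
    uniq = sorted(pd.unique(labels.dropna()))
    if len(uniq) != 2:
        raise ValueError("RTK naming requires exactly 2 clusters")
    for g in list(egfr_genes) + list(erbb3_genes):
        if g not in m.index:
            raise ValueError(f"marker gene {g!r} missing from matrix")
    contrast = m.loc[list(egfr_genes)].mean(axis=0) - m.loc[list(erbb3_genes)].mean(
        axis=0
    )
    means = {c: float(contrast[labels == c].mean()) for c in uniq}
    high = max(uniq, key=lambda c: means[c])
    return {c: (RTK_HIGH if c == high else RTK_LOW) for c in uniq}


def integrate_subtypes(rtk_label: str, phenotype: str) -> str:
    """Combine an RTK label and a phenotype call into the integrated subtype."""
    valid_rtk = {RTK_HIGH, RTK_LOW, UNDETERMINED}
    valid_phen = {"Invasive", "Proliferative", UNDETERMINED}
    if rtk_label not in valid_rtk:
        raise ValueError(f"unknown RTK label {rtk_label!r}")
    if phenotype not in valid_phen:
        raise ValueError(f"unknown phenotype label {phenotype!r}")
    if rtk_label == UNDETERMINED or phenotype == UNDETERMINED:
        return "Unassigned"
    if rtk_label == RTK_HIGH:
        return "S1" if phenotype == "Invasive" else "Discordant"
    return "S2" if phenotype == "Invasive" else "S3"
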