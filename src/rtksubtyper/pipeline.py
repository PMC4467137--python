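"""End-to-end subtype discovery and validation workflows.

``discover`` runs the class-discovery chain on one cohort: optional batch
merging, expressed/silenced calling, prevalence filtering, hierarchical and
consensus clustering of the RTK genes at k=2, silhouette screening (negative
width -> undetermined), phenotype calls against invasive/proliferative
centroids, integration into the three subtypes, and cross-validated
centroid-signature selection on the assigned samples.

``validate`` applies a fitted signature to an external cohort: batch merging,
clustering on the available signature genes at k=3, silhouette screening and
a permutation test of subtype correspondence against the discovery labels.

Both record every parameter and seed in a manifest so a run can be
reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clanc import CentroidSignature, CvReport, clanc_classify, clanc_fit, cv_select_size
from .cluster import (
    ConsensusResult,
    SilhouetteResult,
    consensus_cluster,
    cut_clusters,
    hier_cluster,
    pearson_distance,
    silhouette_widths,
)
from .phenotype import (
    PhenotypeCentroids,
    call_phenotypes,
    integrate_subtypes,
    name_rtk_clusters,
)
from .preprocess import call_expressed, combat_adjust, filter_by_prevalence
from .submap import CorrespondenceResult, subtype_correspondence

log = logging.getLogger("rtksubtyper")

__all__ = ["DiscoveryResult", "ValidationResult", "discover", "validate"]


@dataclass
class DiscoveryResult:
    calls: pd.DataFrame  # per sample: rtk cluster, rtk label, r_inv, r_prol, phenotype, integrated
    expressed_features: list[str]
    consensus: ConsensusResult
    silhouette: SilhouetteResult
    cv_report: CvReport | None
    signature: CentroidSignature | None
    manifest: dict

    @property
    def assigned(self) -> pd.Series:
        mask = self.calls["integrated"].isin(["S1", "S2", "S3"])
        return self.calls.loc[mask, "integrated"]


@dataclass
class ValidationResult:
    cluster_labels: pd.Series
    signature_calls: pd.DataFrame
    consensus: ConsensusResult
    silhouette: SilhouetteResult
    correspondence: CorrespondenceResult
    genes_used: list[str]
    manifest: dict


def _manifest(stage: str, params: dict) -> dict:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return {
        "tool": f"rtksubtyper {__version__}",
        "stage": stage,
        "params": params,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
    }


def discover(
    matrix: pd.DataFrame,
    rtk_genes: Sequence[str],
    centroids: PhenotypeCentroids,
    batches: pd.Series | None = None,
    *,
    k_rtk: int = 2,
    prevalence: float = 0.05,
    consensus_iterations: int = 1000,
    feature_fraction: float = 0.8,
    phenotype_cutoff: float = 0.4,
    clanc_grid: Sequence[int] = range(1, 201),
    folds: int = 5,
    seed: int = 0,
    egfr_genes: Sequence[str] = ("EGFR",),
    erbb3_genes: Sequence[str] = ("ERBB3",),
    detection_method: str = "global_mixture",
    detection_threshold: float | None = None,
    fit_signature: bool = True,
) -> DiscoveryResult:
    """Run the full class-discovery workflow on one expression cohort."""
    params = {
        "k_rtk": k_rtk,
        "prevalence": prevalence,
        "consensus_iterations": consensus_iterations,
        "feature_fraction": feature_fraction,
        "phenotype_cutoff": phenotype_cutoff,
        "clanc_grid": [int(min(clanc_grid)), int(max(clanc_grid))],
        "folds": folds,
        "seed": seed,
        "detection_method": detection_method,
        "n_samples": matrix.shape[1],
        "n_genes": matrix.shape[0],
        "batched": batches is not None,
    }
    if batches is not None:
        log.info("merging %d batches with empirical-Bayes adjustment", batches.nunique())
        matrix = combat_adjust(matrix, batches)

    detection = call_expressed(
        matrix, method=detection_method, threshold=detection_threshold, seed=seed
    )
    expressed = filter_by_prevalence(detection, prevalence)
    log.info("%d/%d features expressed in >= %.0f%% of samples",
             len(expressed), matrix.shape[0], 100 * prevalence)
    if len(expressed) < 10:
        raise RuntimeError(
            f"clustering stage aborted: only {len(expressed)} expressed "
            "feature(s) after prevalence filtering (need >= 10)"
        )
    kept = matrix.loc[expressed]

    rtk_present = [g for g in rtk_genes if g in kept.index]
    if len(rtk_present) < 2:
        raise RuntimeError(
            "clustering stage aborted: fewer than 2 RTK genes survive the "
            "expression filter"
        )
    rtk_matrix = kept.loc[rtk_present]
    dist = pearson_distance(rtk_matrix)
    hc_labels = pd.Series(
        cut_clusters(hier_cluster(dist), k_rtk), index=matrix.columns, name="rtk_cluster"
    )
    consensus = consensus_cluster(
        rtk_matrix, k_rtk, iterations=consensus_iterations,
        feature_fraction=feature_fraction, seed=seed,
    )
    sil = silhouette_widths(dist, hc_labels)
    naming = name_rtk_clusters(matrix, hc_labels, egfr_genes, erbb3_genes)
    rtk_label = hc_labels.map(naming)
    rtk_label[sil.widths < 0] = "Undetermined"

    cent_present = [g for g in centroids.genes if g in matrix.index]
    if len(cent_present) < len(centroids.genes):
        log.warning(
            "only %d/%d phenotype signature genes available",
            len(cent_present), len(centroids.genes),
        )
        keep_mask = np.isin(centroids.genes, cent_present)
        centroids = PhenotypeCentroids(
            genes=cent_present,
            invasive=centroids.invasive[keep_mask],
            proliferative=centroids.proliferative[keep_mask],
        )
    phen = call_phenotypes(matrix, centroids, phenotype_cutoff)
    integrated = pd.Series(
        [
            integrate_subtypes(rtk_label[s], phen.loc[s, "phenotype"])
            for s in matrix.columns
        ],
        index=matrix.columns,
        name="integrated",
    )
    calls = pd.DataFrame(
        {
            "rtk_cluster": hc_labels,
            "rtk_label": rtk_label,
            "silhouette": sil.widths,
            "r_inv": phen["r_inv"],
            "r_prol": phen["r_prol"],
            "phenotype": phen["phenotype"],
            "integrated": integrated,
        }
    )

    cv_report = signature = None
    assigned = integrated[integrated.isin(["S1", "S2", "S3"])]
    if fit_signature:
        train = kept[assigned.index]
        cv_report = cv_select_size(train, assigned, grid=clanc_grid, folds=folds, seed=seed)
        signature = clanc_fit(train, assigned, cv_report.chosen)
        log.info(
            "signature: %d genes/class (CV error %.3f)",
            cv_report.chosen,
            min(cv_report.errors),
        )
    return DiscoveryResult(
        calls=calls,
        expressed_features=expressed,
        consensus=consensus,
        silhouette=sil,
        cv_report=cv_report,
        signature=signature,
        manifest=_manifest("discover", params),
    )


def validate(
    matrix: pd.DataFrame,
    signature: CentroidSignature,
    discovery_matrix: pd.DataFrame,
    discovery_labels: pd.Series,
    batches: pd.Series | None = None,
    *,
    k: int = 3,
    consensus_iterations: int = 1000,
    feature_fraction: float = 0.8,
    n_marker: int = 50,
    n_perm: int = 500,
    seed: int = 0,
) -> ValidationResult:
    """Validate a signature on an external cohort and map its clusters back."""
    params = {
        "k": k,
        "consensus_iterations": consensus_iterations,
        "feature_fraction": feature_fraction,
        "n_marker": n_marker,
        "n_perm": n_perm,
        "seed": seed,
        "n_samples": matrix.shape[1],
    }
    if batches is not None:
        matrix = combat_adjust(matrix, batches)

    present = [g for g in signature.genes if g in matrix.index]
    frac = len(present) / len(signature.genes)
    if frac < 0.5:
        raise RuntimeError(
            f"only {len(present)}/{len(signature.genes)} signature genes "
            "present (< 50%); aborting validation"
        )
    if frac < 1.0:
        log.warning(
            "only %d/%d signature genes available in the external cohort",
            len(present), len(signature.genes),
        )
    sub = matrix.loc[present]
    dist = pearson_distance(sub)
    labels = pd.Series(
        cut_clusters(hier_cluster(dist), k), index=matrix.columns, name="cluster"
    )
    consensus = consensus_cluster(
        sub, k, iterations=consensus_iterations,
        feature_fraction=feature_fraction, seed=seed,
    )
    sil = silhouette_widths(dist, labels)
    calls = clanc_classify(signature, matrix) if frac == 1.0 else clanc_classify(
        _restrict_signature(signature, present), matrix
    )
    correspondence = subtype_correspondence(
        discovery_matrix,
        discovery_labels,
        matrix,
        labels,
        n_marker=n_marker,
        n_perm=n_perm,
        seed=seed,
    )
    return ValidationResult(
        cluster_labels=labels,
        signature_calls=calls,
        consensus=consensus,
        silhouette=sil,
        correspondence=correspondence,
        genes_used=present,
        manifest=_manifest("validate", params),
    )


def _restrict_signature(sig: CentroidSignature, present: Sequence[str]) -> CentroidSignature:
    present = set(present)
    active = {c: [g for g in sig.active_sets[c] if g in present] for c in sig.classes}
    union = [g for c in sig.classes for g in active[c]]
    return CentroidSignature(
        classes=sig.classes,
        active_sets=active,
        genes=union,
        class_centroids=sig.class_centroids.loc[union],
        overall_centroid=sig.overall_centroid.loc[union],
        pooled_sd=sig.pooled_sd.loc[union],
        s0=sig.s0,
        class_counts=sig.class_counts,
        genes_per_class=sig.genes_per_class,
    )
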