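# rtksubtyper

Melanoma tumors fall into transcriptional subtypes with sharply different
sensitivity to BRAF inhibition. Clustering samples on the expression of
receptor tyrosine kinase (RTK) genes splits them into an EGFR-high/ERBB3-low
group and an EGFR-low/ERBB3-high group; intersecting that split with the
invasive-vs-proliferative phenotype (the MITF-low/AXL-high versus MITF-high
axis) yields three reproducible subtypes, of which the
EGFR^HIGH/ERBB3^LOW-Invasive one is intrinsically resistant to BRAF
inhibitors. `rtksubtyper` implements that whole discovery-and-validation
workflow as a tested Python package, together with the drug-response analysis
used to characterize the subtypes, and a synthetic-data generator that plants
the same structure with known ground truth so every stage is verifiable.

The package is for computational biologists who want to run, extend or
stress-test this class-discovery recipe on their own expression cohorts.

## What it computes

- **Preprocessing** — probe-to-gene collapsing by maximal inter-quartile
  range; expressed/silenced calling via a global two-component Gaussian
  mixture (posterior ≥ 0.5); prevalence filtering (keep genes expressed in
  ≥ 5% of samples); merging of independent cohorts with parametric
  empirical-Bayes batch correction (the ComBat location/scale model,
  verified against the Bioconductor reference to machine precision).
- **Clustering** — distance d(i,j) = 1 − Pearson r between sample profiles,
  agglomerative average linkage (UPGMA), consensus clustering over random
  80% feature subsets (co-clustering frequencies), and Rousseeuw silhouette
  widths; samples with s(i) < 0 are flagged undetermined.
- **Phenotype calls** — Pearson correlation of each sample with invasive and
  proliferative centroids; with cutoff c = 0.4 a sample is Invasive iff
  r_inv ≥ c and r_inv − r_prol ≥ c (Proliferative symmetrically), otherwise
  Undetermined. RTK cluster × phenotype integrate into the three subtypes.
- **Gene signature** — class-specific nearest-centroid selection (ClaNC
  style): per gene and class, d_kg = (mean_kg − mean_g)/(m_k (s_g + s0)) with
  m_k = sqrt(1/n_k + 1/n); disjoint active gene sets chosen by iterated
  global argmax of |d|; signature size picked by stratified five-fold
  cross-validation (lowest error, then fewest genes).
- **Cross-cohort correspondence** — a permutation-based subclass-mapping
  analog: markers of each cluster (top t-statistic genes) are tested for
  rank enrichment in the other cohort's cluster-vs-rest ranking, in both
  directions, with BH-FDR across cluster pairs.
- **Association statistics** — per-gene one-way ANOVA with BH-FDR, Tukey HSD
  post-hoc, joint FDR/fold-change screens, expression–IC50 Pearson
  correlation with censored IC50s entering at the maximum tested dose, and
  Fisher's exact test.
- **Pharmacology** — four-parameter logistic dose-response fits (variable
  slope, multi-start least squares, IC50 censored at the top tested dose),
  median-effect modeling fa/(1−fa) = (D/Dm)^m, and Chou–Talalay combination
  indices CI = d1/Dx1 + d2/Dx2 with CI < 1 called synergism.

## Worked example

Simulate a 120-sample cohort with three planted subtypes and two batches,
build phenotype centroids from an independent reference cohort, and run the
full discovery workflow:

```python
from sklearn.metrics import adjusted_rand_score
from rtksubtyper import ExpressionSimConfig, generate_expression, discover
from rtksubtyper.phenotype import build_centroids

cohort = generate_expression(ExpressionSimConfig(
    n_samples_per_subtype=(30, 30, 60), n_genes=500,
    marker_effect=3.0, noise_sd=1.0, n_batches=2, seed=11))
reference = generate_expression(ExpressionSimConfig(
    n_samples_per_subtype=(30, 30, 60), n_genes=500,
    marker_effect=3.0, noise_sd=1.0, seed=12))
centroids = build_centroids(reference.matrix, reference.true_phenotype,
                            reference.mpse_genes)
result = discover(cohort.matrix, cohort.rtk_genes, centroids,
                  batches=cohort.true_batch, clanc_grid=range(1, 51), seed=0)

print(result.calls["integrated"].value_counts().to_dict())
assigned = result.assigned
print("assigned fraction:", round(len(assigned) / 120, 3))
print("ARI vs planted truth:",
      round(adjusted_rand_score(cohort.true_subtype.loc[assigned.index], assigned), 3))
print("signature size (genes/class):", result.cv_report.chosen,
      "| min CV error:", min(result.cv_report.errors))
print("mean silhouette:", round(result.silhouette.overall_mean, 3))
```

prints

```
{'S3': 60, 'S1': 30, 'S2': 30}
assigned fraction: 1.0
ARI vs planted truth: 1.0
signature size (genes/class): 3 | min CV error: 0.0
mean silhouette: 0.606
```

All 120 samples are assigned, the integrated labels match the planted
subtypes exactly (adjusted Rand index 1.0), and cross-validation selects a
3-gene-per-class signature with 0% held-out error — on clean synthetic data
the smallest signature attaining zero error wins, by construction of the
size-selection rule. The mean silhouette width of 0.61 indicates compact,
well-separated RTK clusters.

The same stages are available from the shell via the `rtksubtyper` command
(`simulate`, `preprocess`, `cluster`, `phenotype`, `signature`, `submap`,
`assoc`, `drugfit`, `synergy`, `discover`); run `rtksubtyper --help`.

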