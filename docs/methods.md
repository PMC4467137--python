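# Methods

This note documents the models implemented in `rtksubtyper`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where several were possible.

## The subtyping model

The package operationalizes a two-axis view of melanoma transcriptomes.

**Axis 1 (RTK).** Samples are clustered at k = 2 on a panel of receptor
tyrosine kinase genes using the distance 1 − Pearson r between expression
profiles and average-linkage (UPGMA) agglomeration. The two clusters are
named by their mean EGFR-minus-ERBB3 contrast (EGFR_HIGH_ERBB3_LOW vs
EGFR_LOW_ERBB3_HIGH) rather than by arbitrary cluster indices, so the label
assignment is invariant to permutations of the dendrogram. Cluster stability
is quantified by consensus clustering: each of `iterations` (default 1000)
rounds samples ⌈0.8·F⌉ features without replacement (all samples retained),
reclusters, and co-assignment frequencies are accumulated; the final
consensus partition is average-linkage clustering of 1 − consensus cut at
the same k. Per-sample silhouette widths s(i) = (b − a)/max(a, b) screen the
partition; samples with s(i) < 0 are treated as undetermined. Members of
singleton clusters receive s = 0 (the standard convention; the choice only
matters for degenerate partitions).

**Axis 2 (phenotype).** Each sample is correlated with an invasive and a
proliferative centroid over a phenotype signature gene list. With cutoff
c (default 0.4):

- Invasive: r_inv ≥ c and r_inv − r_prol ≥ c
- Proliferative: r_prol ≥ c and r_prol − r_inv ≥ c
- Undetermined: otherwise.

The gap condition uses the *signed* difference. An absolute-value reading
would let a sample with r_inv = 0.4, r_prol = 0.9 satisfy both positive
clauses simultaneously; the signed form makes the three classes a partition
of the (r_inv, r_prol) plane and is mirror-symmetric under swapping the two
centroids. The cutoff is a free parameter; 0.4 is the default.

**Integration.** (EGFR_HIGH, Invasive) → S1; (EGFR_LOW, Invasive) → S2;
(EGFR_LOW, Proliferative) → S3. Any undetermined input yields Unassigned.
The combination (EGFR_HIGH, Proliferative) is biologically unexpected and is
flagged Discordant instead of being silently dropped; integration is a total
function over its label domain. Unassigned samples are excluded from
signature training but still receive a signature-based call afterwards.

## Batch correction

`combat_adjust` implements the parametric empirical-Bayes location/scale
model: genes are standardized against a design of batch indicators plus any
protected covariates, per-batch location (γ) and scale (δ²) estimates are
shrunk toward a normal / inverse-gamma prior by the standard iterative
posterior solution (convergence 1e-4 on the estimates, ≤ 100 iterations),
and the data are back-transformed. The implementation reproduces the
Bioconductor reference (`sva::ComBat`, parametric priors) to ~1e-14, which
the test suite verifies by invoking `Rscript` on a small simulated cohort.

Two behavioral notes, both properties of the algorithm rather than of this
implementation:

- The grand per-gene mean is *approximately* preserved under balanced
  batches (median shift ~1e-3), not exactly: gene-wise shrinkage moves the
  two batch means by slightly different amounts.
- A per-gene batch F-test on corrected data rejects far *below* the nominal
  rate (essentially 0%): the correction equalizes the estimated batch means,
  so the post-hoc F statistic is deflated relative to its null distribution.
  Corrected data should not be mistaken for fresh null data.

Genes with zero variance inside any batch cannot be standardized and are
passed through unadjusted with a warning. Singleton batches are an error.

## Expression calling

The expressed/silenced dichotomy is obtained from a two-component Gaussian
mixture fitted to all matrix values, calling an entry expressed when the
posterior of the higher-mean component is ≥ 0.5. This is a self-contained
stand-in for reference-corpus barcode methods, which require platform-wide
training arrays; it captures the bimodal silenced/expressed structure of
log2 microarray data but is not numerically equivalent to frozen-RMA
barcoding. A fit needs ≥ 20 samples; degenerate fits (vanishing component
weight or variance, coincident means) fall back to a fixed threshold at the
grand median with a warning. The prevalence filter keeps features expressed
in at least `min_fraction` of samples, inclusive (so 3/58 ≈ 5.17% passes a
5% cutoff and 2/58 ≈ 3.45% does not).

## Signature selection (nearest centroids with class-specific genes)

For gene g and class k,

    d_kg = (x̄_kg − x̄_g) / (m_k · (s_g + s0)),   m_k = √(1/n_k + 1/n),

where s_g is the pooled within-class standard deviation and the
stabilization constant s0 is the median of all s_g (the common
shrunken-centroid convention, which keeps low-variance genes from dominating
the ranking). Genes are assigned to classes by iterated global argmax over
|d|: the largest remaining (gene, class) statistic claims its gene, each
gene serves at most one class, each class holds at most `genes_per_class`
genes — so when one gene tops two classes it goes to the class with the
larger |d| and the next-ranked gene fills the other. Classification
minimizes the standardized squared distance over the union of active genes,
with class k represented by its own centroid on its active genes and by the
overall centroid elsewhere; ties break toward the larger training class,
then label order, and are flagged.

The signature size is chosen by stratified five-fold cross-validation over a
grid (default 1–200 genes per class, capped so the signature fits the gene
pool): lowest mean held-out error wins, ties resolve to the smallest size.
On cleanly separable synthetic data this legitimately selects very small
signatures (zero CV error is reached at one gene per class); real, noisy
cohorts push the optimum to larger sizes.

## Cross-cohort correspondence

`subtype_correspondence` is a functional analog of subclass mapping, not a
numerical clone of the GSEA-based original. For clusters a (cohort A) and
b (cohort B): the markers of a are the top `n_marker` (default 50) genes by
pooled-variance t statistic a-vs-rest in A; the statistic is the mean rank
of those markers in B's b-vs-rest t ranking; the null is built by permuting
B's sample labels (`n_perm`, default 500; add-one estimator, so p ≥
1/(n_perm+1)); the test is repeated with roles swapped and p_ab is the
worse of the two directions; BH-FDR is applied across all k_A × k_B pairs.
Enrichment is one-sided (markers up in the matched class), matching the
subtype-marker use case. Permutation-based p-values on small cohorts have
coarse resolution; with fewer than ~100 permutations the function warns.

## Association statistics

One-way fixed-effects ANOVA per gene with BH adjustment across genes; genes
with zero between- and within-group variance get p = 1 and a flag, genes
with real separation but zero within-group variance get p = 0. Tukey HSD
provides pairwise post-hoc p-values and is intended to be run only when the
adjusted overall p clears the gate (the function itself is unconditional).
The FDR/fold-change screen passes a gene iff q < `fdr_max` and the largest
pairwise linear fold-change 2^|Δmean| (data are log2) is ≥ `fc_min` in at
least one contrast; all pairwise contrasts are considered. Expression–drug
response correlations are Pearson with the two-sided t approximation;
censored IC50 values enter at their cap and the censored count is recorded.
All tests are two-sided.

## Pharmacology

The 4PL viability model is y(D) = bottom + (top − bottom)/(1 + (D/IC50)^h),
h > 0 for inhibition curves (equivalent to the GraphPad variable-slope form
with a negative Hill slope). Fitting is multi-start bounded least squares
(7 initial log10 IC50 values spanning the tested dose range × slopes
{0.5, 1, 3}); the returned solution is never worse than any start. Default
bounds bottom ∈ [0, 0.5] and top ∈ [0.5, 1.2] encode fraction-of-control
semantics and prevent degenerate flat fits; both are overridable. When the
fitted IC50 exceeds the largest tested dose, the curve never reaches
half-effect in range and the IC50 is reported censored at that dose. At 5%
viability noise the IC50 and the bottom asymptote trade off, so individual
fits can err by tens of percent while the estimator is accurate in
aggregate; accuracy claims are therefore made on means across replicate
experiments.

The median-effect model fa/(1−fa) = (D/Dm)^m is fitted by least squares on
the log-odds plot; points with fa outside (0.01, 0.99) carry almost no
information on that scale and are clipped out with a warning. The
combination index for an observation (d1, d2, fa) is CI = d1/Dx1 + d2/Dx2
with Dx_i = Dm_i (fa/(1−fa))^(1/m_i) — the two-term, mutually nonexclusive
form. Calls: synergism below 1 − 0.05, additivity within ±0.05 of 1,
antagonism above; CI is invariant to consistent rescaling of dose units.
Because fa enters through log-odds, CI estimates at extreme fa are noisy and
slightly biased upward under viability noise; synergy levels are best read
as means over an fa grid and over replicate experiments.

## The synthetic-data generator

`generate_expression` plants, on a log2 scale:

- **Seven canonical RTK genes** (AXL, EGFR, EPHA2, ERBB3, MERTK, PDGFRA,
  PDGFRB) with subtype direction patterns encoded as weights (±1 strong,
  ±0.5 moderate) scaled by `marker_effect`/2, so a strong-high vs strong-low
  contrast equals `marker_effect` (default 3 log2 units).
- **RTK-like panel genes** (default 27, for a 34-gene panel) echoing a
  canonical pattern with attenuation U(0.5, 1). Echo patterns are sampled
  with weights favoring the EGFR/ERBB3-type mutually exclusive axis
  (weights 3 for EGFR/ERBB3 patterns, 2.5 for PDGFR, 0.5 for AXL, EPHA2 and
  MERTK): a broad receptor panel whose dominant two-cluster split is the
  EGFR/ERBB3 axis, with AXL/MERTK as a secondary axis. With equal weights
  the k = 2 split degenerates into a coin flip between "S1 vs rest" and
  "proliferative vs rest", which is not the regime the workflow addresses.
- **A shared invasive program** (default 20 genes) high in both invasive
  subtypes and low in the proliferative one, plus **three disjoint marker
  blocks** (default 30 genes each) high in exactly one subtype. The
  phenotype signature (`SimulatedDataset.mpse_genes`) is the invasive
  program plus the proliferative block — genes separating the phenotypes
  without discriminating S1 from S2, which is what makes
  centroid-correlation phenotype calls well-posed.
- **Background genes** drawn once per gene from a silenced/expressed
  mixture (means 4 and 8, P(expressed) = 0.6), constant across subtypes.
- **Batch effects**, gene-wise per batch: additive shifts γ ~ N(0,
  `batch_shift_sd`) and multiplicative scales exp(N(0, `batch_scale_sd`))
  applied to the noise term — exactly the location/scale model the EB
  correction assumes, making correction a well-posed recovery problem.
  Batches interleave within subtype so design and batch are not confounded.

Default subtype sizes (11, 9, 25) mirror the unbalanced ~25/20/55% subtype
prevalence of melanoma cell-line panels. Noise is i.i.d. Gaussian (default
sd 1 log2 unit). Given a seed, generation is bit-reproducible.

Dose-response simulation draws from the median-effect or 4PL model over the
7-point dilution series 0.004–16 μM, with truncated-Gaussian viability noise
(triplicates by default). Combination tables are constructed to satisfy
Loewe additivity exactly (sham pairs reduce to the single-drug curve at the
summed dose); a synergy factor f multiplies the dose needed for every effect
level, so the generated combination has CI = f by construction.

**What the generator does not emulate:** probe-level structure, platform
differences beyond location/scale, correlated gene-gene noise within
programs, heteroscedastic or intensity-dependent noise, partially
overlapping gene universes, intra-tumor heterogeneity of clinical samples,
and heteroscedastic viability noise. Tests passing on these simulations
therefore demonstrate correctness of the algorithms under the stated model,
not performance guarantees on real cohorts — in particular, real data will
yield larger signatures, lower silhouettes and weaker correspondence FDRs
than the clean synthetic runs.

## Problem sizes and numerical conventions

The test suite and the acceptance script run cohorts of 45–120 samples with
300–500 genes, 100–1000 consensus iterations, 500-permutation
correspondence nulls and 20-replicate dose-response batteries; these sizes
keep every stage's behavior measurable while each suite run stays in the
minutes range on one CPU. Other conventions: quartiles for the IQR probe
collapse are linear-interpolation (type 7) with ties broken toward the
lexicographically smaller probe id; UPGMA merge ties break toward the
lowest-index pair; consensus matrices are validated (symmetry, unit
diagonal, [0,1] range) on every run; missing values in input matrices are an
error, never imputed.
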