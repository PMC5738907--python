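# Methods

This note documents the statistical models and numerical choices behind
`tamont`: what each stage assumes, which knobs matter, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## 1. Single-cell preprocessing and cell classification

**Quality control.** Cells are retained when they detect at least
`min_genes` genes (default 800) and carry at least `min_reads` total
counts (default 50,000). Both thresholds are inclusive. Total counts stand
in for uniquely aligned reads whenever no alignment metadata exists; the
two are monotonically related, so the substitution preserves the ranking
the threshold acts on. Filtering is idempotent.

**Normalization.** Counts are scaled to counts per million (CPM) per cell;
cells with zero totals are excluded with a warning rather than silently
producing NaNs. Log expression is defined as log2(CPM/10 + 1). The /10
pseudo-scaling damps the inflation of low counts that a plain log2(CPM+1)
produces at single-cell depth.

**CNV quantification.** Copy-number evidence per cell and per called
segment is the mean, over the segment's genes, of the control-referenced
z-score of log expression: (x − mean_control) / max(sd_control, 0.1). The
SD floor (0.1 log2 units) prevents division blow-ups on low-variance
genes. No genome smoothing or windowing is applied beyond the segment
itself — a deliberate simplification of sliding-window approaches; it is
adequate because segments are provided by exome-level calls and span many
genes. Segments overlapping fewer than 5 measured genes are reported as
missing, not zero.

**Classification.** A cell is called neoplastic if it shows ≥ 1 expressed
clonal SNV with ≥ 2 alt reads (the 2-read floor guards against single-read
errors), or if its CNV evidence is strong: mean |segment score| > 0.5 with
direction concordance ≥ 2/3 against the exome amp/del calls. Mutation and
CNV evidence take precedence over marker expression. A non-neoplastic cell
is a TAM when the mean log2(CPM/10+1) over the marker panel (default
PTPRC, ITGAM, AIF1, CD14, CSF1R, HLA-DRA; configurable) exceeds 1.0;
otherwise it is unassigned. Control cells for CNV scoring are chosen
provisionally as marker-positive, mutation-free cells, the in-silico
analog of a non-malignant control sample.

## 2. Signature derivation

**Feature selection.** Candidates are human homologues of genes
differential between blood-derived and microglial TAMs in *both* murine
lineage-tracing models (consistent sign, adjusted p below the table's
cutoff), restricted to genes with mean CPM strictly above 1 in the human
TAMs. Strict inequality at the boundary.

**Transforms.** log2(CPM/10+1), then per-gene z-scoring within each
capture platform independently. Platform z-scoring absorbs any constant
per-platform offset exactly (a tested invariance), which is what makes the
two platforms co-analyzable; genes constant within a platform are set to
zero there and flagged.

**PCA with Varimax rotation.** Ten components are retained before
rotation (only PC1 is consumed downstream; the choice is inert beyond
providing the rotation with a subspace). Loadings are on the
**component-correlation scale** — eigenvector × singular value / √(n−1) —
which for z-scored input equals the gene-component correlation. This is
the only scale on which a fixed |loading| > 0.2 threshold can select a
~66-gene signature: unit-norm eigenvector loadings are bounded by
Σℓ² = 1 per component and cannot hold 66 entries above 0.2. Varimax is
Kaiser-normalized, tolerance 1e-9, ≤ 1000 sweeps; the rotation matrix is
orthogonal to 1e-8 and rotation never lowers the Varimax criterion.
Components are re-ordered by post-rotation explained variance and
sign-fixed so each component's largest-|loading| gene loads positively;
biological orientation is *never* taken from this convention.

**Mixture partition.** PC1 scores are partitioned by a two-component 1-D
Gaussian mixture (EM, tolerance 1e-8, ≤ 500 iterations, 10 k-means-seeded
restarts, variance floor 1e-6). The overlap statistic is
∫ min(π₁φ₁, π₂φ₂) dx by trapezoid quadrature over mean ± 8 SD (20,001
points); it equals 0.5 exactly for coincident components and is the
working analog of the "< 5% intersection" criterion.

**Extraction and orientation.** Genes with |PC1 loading| strictly above
0.2 form the signature. The loading-sign → lineage map is decided by a
two-sided Fisher exact test on the 2×2 table of loading sign × murine
lineage over all candidate genes: the sign direction enriched for murine
blood-derived markers is labeled blood-derived. If the enrichment is
ambiguous (p > 0.1) the pipeline refuses to orient rather than guessing.

**MFA.** Tables (cells × genes, z scale) are each divided by their first
singular value, stacked over cells, and decomposed by PCA; the partial
inertia of a table is the summed squared scores of its cells over all
retained components, and the reported ratio is table1/table2 in input
order. First-singular-value scaling makes the ratio exactly 1 for a
duplicated table and for a globally rescaled copy.

**Consensus clustering.** An SC3-style scheme, reimplemented: three
cell-cell distances (Euclidean, Pearson, Spearman) × two spectral
transforms (PCA of the distance matrix; eigenvectors of its normalized
graph Laplacian) × k-means (10 restarts) over four leading-dimension
counts spanning 4–7% of n; binary co-clustering matrices are averaged and
the consensus matrix is cut by complete-linkage hierarchical clustering at
k = 2. Beyond 1000 cells a seeded subsample is clustered and remaining
cells are assigned to the nearest consensus-cluster centroid in gene
space. Deterministic under a fixed seed.

**Agreement.** The Matthews correlation coefficient between binary
labelings is maximized over the two label matchings, since cluster labels
are arbitrary; degenerate single-class labelings return 0 with a warning.

## 3. Group comparison

**Differential expression.** A negative-binomial Wald test in the classic
bulk-RNA-seq mold, reimplemented: median-of-ratios size factors (the
geometric-mean reference uses each gene's positive counts, a necessity
with sparse data; total-count scaling is the fallback); per-gene
method-of-moments dispersions from the pooled within-group variance,
shrunk 50/50 on the log scale toward a fitted a₀ + a₁/μ mean-dispersion
trend; the contrast is the log ratio of moderated group means
(+0.5/n pseudo-events keep it finite), with the delta-method variance
(1/μ + α)/n per group and a t reference with n₁+n₂−2 degrees of freedom
— slightly heavier-tailed than the normal, which keeps the far tail
honest when BH is applied over thousands of genes. The contrast is the
lexicographically second group over the first, making label-swap
equivariance exact. All-zero genes are excluded.

**Co-occurrence.** Detection is binarized at CPM > 0 (the co-expression
statements are presence statements; the threshold is configurable). Odds
ratios use the Haldane–Anscombe +0.5 on all four cells when any cell is
zero; p values are two-sided Fisher exact on the uncorrected table
(defined, as throughout, by summing hypergeometric probabilities ≤ the
observed table's); BH adjustment spans all reported pairs. The exact
co-occurrence statistic used by network-style analyses varies between
implementations; Fisher + Haldane is this package's choice and is
labeled as such.

## 4. Bulk cohorts and survival

Per-sample lineage scores are unweighted means of each lineage's
signature genes on the log2(CPM+1) scale, z-scored across the cohort
(missing genes are logged; only a complete miss is an error). Subtypes are
compared by Tukey's range test (studentized-range adjusted p). Survival
uses a median split of the score — "high" strictly above the median, ties
low, since a bare above/below-the-median rule fixes no tie behavior —
followed by a Cox proportional-hazards model of the stratum indicator
with age and a male-indicator gender covariate (reference: female), Efron
tie handling, Wald p, and Kaplan–Meier step tables per stratum.
Z-scoring before or after the split is immaterial to the split (monotone
transform); scores are z-scored first here. Cohorts (e.g. GBM vs LGG) are
analyzed as separate runs, not as a stratified model.

## 5. Regional mapping

Samples are scored by the mean per-gene z over each lineage's signature
genes; per-structure enrichment uses a one-vs-rest two-sided Mann–Whitney
test per lineage, BH-adjusted across structure × lineage tests, with the
difference of mean scores as effect size. Such enrichment is often read
qualitatively off z-score heatmaps; the rank-sum stage makes it a formal
test and is labeled as an extension. Samples sharing a tumor are not
independent; the test ignores this (recorded as a caveat in the output),
and the planted tumor random effect in the simulation makes the test
mildly conservative rather than anticonservative because tumors span
structures.

## 6. The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Cohort geometry:** 19 samples × 200 cells, two platforms ("C1" — full
  length, deeper, higher detection; "SmartSeq2") split 50/50 across
  samples; ~20% neoplastic cells; 70% of TAMs blood-derived. After QC this
  yields ≈ 3000 TAMs.
* **Counts:** negative binomial (dispersion 0.3) on per-cell expected
  proportions × a per-platform log-normal library size (log-means
  log 3×10⁵ and log 2×10⁵, σ = 0.35), followed by Bernoulli detection
  thinning whose success probability rises from the platform floor (0.75 /
  0.55) toward 1 with expected counts — highly expressed genes do not
  drop out, as on real platforms. 3% of cells have degraded (×0.04)
  libraries to exercise QC.
* **Lineage signal:** 66 of 237 candidate genes carry a ±effect_size/2
  log2 shift between lineages (33 per lineage). The default effect_size is
  3.0 (8-fold) — core ontogeny markers are near on/off between lineages.
  The remaining 171 candidates are lineage-specific in mouse only; a
  further 33 mapped murine genes point at silenced human genes to
  exercise the mean-CPM filter, and the murine table funnels 836 → 300
  dual-model genes → 270 mapped → 237 expressed, a realistic attrition
  funnel for cross-species marker transfer.
* **Neoplastic cells:** a 120-gene upregulated program, suppressed
  macrophage markers, CNV segments (default 4, 30 contiguous genes each
  on a synthetic genome of 1 Mb-spaced loci, alternating amp/del, fold 2)
  scaling expression, and ~25 clonal SNVs whose alt reads are observed
  per cell with probability 0.5 (alt ≥ 2 when observed); TAMs show sparse
  reference-only coverage and a rare (0.5%) single-read artifact.
* **Bulk cohorts:** blood content is bimodal (Beta(12,4) vs Beta(4,12) in
  two equal groups) so the planted hazard strata coincide with the top
  half of blood content; blood genes rise with content and microglial
  genes with its complement (slope 2 log2 units, noise SD 0.5); survival
  is exponential with the hazard multiplied by true_hr (default 3.44) in
  the high group and a mild age effect (+2%/year), with exponential
  censoring targeting the requested censor fraction (default 0.3).
* **Regional atlas:** six canonical structures, 8 samples each, signed
  blood bias in z units (+1.5 vascular structures, +1.0 peri-necrotic,
  −1.5 leading edge, −1.0 infiltrated white matter), a tumor random
  intercept (SD 0.25) with tumors spanning structures, z-scored per gene.
* **Determinism:** one master seed; stage-specific child streams are
  spawned with fixed keys, so every artifact (including MTX bytes) is
  identical under the same seed.

**What the generator does not emulate:** doublets, ambient RNA,
cell-cycle structure, read-level data, batch chemistry beyond the
platform offsets, expression-dependent mutation coverage, or the
continuum of intermediate lineage states reported in some tumors. Under
the default (strong) planted contrast the two populations separate almost
perfectly — mixture overlap is numerically zero and classifier agreement
near 1 — so passing tests demonstrate correctness of the machinery under
clearly separated lineages, not performance on marginal, continuum-like
data.

## 7. Problem sizes in the shipped checks

The test suite runs the full default cohort for 10 seeds and the survival
recovery for 50 cohorts of n = 363; unit tests use a scaled-down study
(6 samples × 120 cells, 800 genes, 120 candidates) with correspondingly
scaled QC thresholds. `scripts/acceptance.py` averages 3 full pipeline
runs, 50 survival cohorts per condition, 5 DE runs per condition, and 10
regional atlases per condition — sizes chosen to keep every estimate's
Monte-Carlo error well inside the margins being checked.

## 8. Known limitations

* The NB-Wald DE test is a transparent reconstruction of the classic
  estimator family, not a drop-in reimplementation of any specific tool;
  its calibration is verified empirically (null FDP, pooled FDR, power)
  rather than inherited.
* The CNV score omits genome smoothing; very short segments (< 5 genes)
  are unscoreable by design.
* MFA partial inertias are computed over all retained components of the
  stacked solution; with tables of unequal cell counts the ratio reflects
  table sizes as well as structure.
* The regional enrichment test treats intra-tumor samples as independent
  (conservative under the simulated design, but not guaranteed so for
  arbitrary designs).
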