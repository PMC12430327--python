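# Methods

This package implements a complete desk-scale analysis chain for
screening maize inbred panels for low-nitrogen (LN) tolerance and
tracing the trait to candidate genes: phenotype-based tolerance scoring
and classification, a Q+K mixed-model genome-wide association scan,
negative-binomial differential expression, weighted co-expression
module detection, and cross-omics candidate integration with qPCR
validation. A synthetic-cohort generator supplies data with known
ground truth so every stage's statistical behavior can be measured.

## Tolerance screening (fuzzy membership index)

For line *i* and trait *j*, with replicate values averaged per line ×
trait × nitrogen level first:

1. relative value `X_ij = mean(N1) / mean(N2)` (N1 = 0.05 mmol/L low
   nitrogen; N2 = 4 mmol/L normal nitrogen);
2. min–max standardization `P_ij = (X_ij − X_jmin) / (X_jmax − X_jmin)`;
3. weights `W_j = CV_j / Σ_j CV_j`, where `CV_j` is the coefficient of
   variation (sample SD, ddof = 1) of the `X_ij` column — so a trait
   that discriminates strongly among lines in its stress response
   carries more weight. Computing CV on the relative values rather than
   the raw trait is a deliberate choice (the raw-trait variant is
   available via `cv_on="raw"`);
4. composite index `P_i = Σ_j P_ij · W_j ∈ [0, 1]`, higher = more
   tolerant.

Classification uses Ward-linkage hierarchical clustering on Euclidean
distance, cut at k = 3, with classes labelled tolerant / intermediate /
sensitive by descending class-mean index. Clustering operates on the
per-trait membership vector `P_i·` by default (`on="scalar"` clusters
the composite index alone); a fixed-threshold classifier is provided as
an alternative. Lines are sorted by identifier before clustering so the
partition is invariant to input order.

Degenerate inputs are hard errors: a zero normal-N mean (the ratio is
undefined), a constant relative-value column (min–max undefined), or a
constant index (no meaningful partition).

Trait reporting: per-trait/level mean, SD, CV%, N1/N2 mean ratio;
balanced two-way fixed-effects ANOVA (genotype, nitrogen, interaction)
via OLS; Pearson correlations between line-mean trait values with
two-sided p and the conventional star codes (* ≤ 0.05, ** ≤ 0.01,
*** ≤ 0.001).

## GWAS (Q+K mixed linear model)

QC removes SNPs with minor-allele frequency ≤ 0.05 or missingness
≥ 20% (both thresholds at their published values; boundaries chosen so
a 25%-missing SNP fails), then mean-imputes remaining missing dosages —
the simplest choice that is unbiased in expectation. QC is idempotent.

Kinship is the centered realized-relationship (VanRaden) matrix
`K = ZZ'/c` with `Z` the column-centered dosages and
`c = Σ 2p_j(1−p_j)`; eigenvalues are clipped at zero for positive
semidefiniteness. Centering makes K invariant to allele-label flips.

The scan fits `y = μ + Qα + xβ + u + e`, `u ~ N(0, σ²_g K)`,
`e ~ N(0, σ²_e I)`. Variance components are estimated once by REML on
the null (no-SNP) model via the spectral decomposition of K (a grid
over log δ = log σ²_e/σ²_g refined by bounded scalar minimization),
then held fixed while every SNP is tested by a GLS F test in the
rotated, whitened space — the population-parameters-previously-
determined (P3D/EMMAX) approximation. The per-SNP residual scale is
re-estimated in the whitened space, so with K = I and no covariates the
test reduces *exactly* to the ordinary per-SNP F test. Because ancestry
rows sum to one, the Q matrix is collinear with the intercept; rank-
deficient designs drop trailing columns with a warning. Calibration is
verified rather than assumed: null scans give uniform p (KS),
genomic-control λ within [0.9, 1.1] and nominal tail rates.

Significance is called at p ≤ 1e-5 (boundary inclusive, matching
−log10 p ≥ 5); Bonferroni-style alternatives are a caller-side choice
of `p_max`. Candidate windows extend ±500 kb (configurable, e.g.
±50 kb) around each hit as 1-based closed intervals truncated at
position 1; a gene is a candidate when its interval intersects the
window, carrying its anchor SNP and distance (0 if overlapping).
Output order is independent of annotation record order.

LD: unphased chip-style data make haplotype r² unavailable, so r² is
the squared dosage correlation (composite genotypic LD) and D′ comes
from EM haplotype-frequency estimation on the two-locus genotype
table. The decay curve bins pairwise distances and reports the
midpoint of the first bin whose mean r² drops below the threshold
(0.1). Note the generator draws markers independently, so synthetic
panels show only structure-induced background LD — decay curves on
synthetic data are a plumbing check, not a linkage model.

## Differential expression (moment-based NB Wald test)

Counts are normalized by median-of-ratios size factors (geometric-mean
reference; total-count fallback when no gene is positive everywhere).
FPKM = count · 1e9 / (length · library size).

The test is deliberately a transparent moment-based construction, not
a re-implementation of any published package's empirical-Bayes
machinery: per-gene dispersion α is estimated by pooled within-group
method-of-moments under Var = μ + αμ², shrunk 50/50 toward a lowess
trend on log mean expression; the Wald statistic is the log2 fold
change over a delta-method SE, referred to the standard normal, with
BH adjustment across genes. A t reference with n₁+n₂−2 df was
evaluated and rejected: with shrunken moment dispersions it is badly
conservative (null type-I ≈ 0.013 at α = 0.05 and essentially no power
at the published thresholds), whereas the normal reference calibrates
correctly (measured null type-I ≈ 0.06, empirical FDR below nominal
with ≥ 80% power at |log2FC| = 2, dispersion 0.1, three replicates).
A prior count of 0.5 keeps fold changes finite for zero groups;
genes with zero counts across a contrast are excluded.

DEG calling uses |log2FC| ≥ 1 (inclusive) with FDR < 0.05 by default;
the raw-p < 0.05 variant of the same thresholds is exposed because
both appear in practice. The four default contrasts compare low vs
normal nitrogen within material (tolerant NT / sensitive NS) × tissue
(leaf L / root R). The Venn decomposition reports all 15 exclusive
membership regions of the four sets plus the 4-way core.

## Co-expression network

Built from scratch: unsigned adjacency `a_ij = |cor|^β` (signed option
`((1+cor)/2)^β`), connectivity `k_i = Σ_{j≠i} a_ij`, topological
overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`
with TOM_ii ≡ 1. Soft-threshold selection computes, per candidate
power, the signed R² of the log10 p(k) vs log10 k regression over
occupied connectivity bins and picks the smallest power reaching 0.8
(argmax fallback). Modules come from average-linkage clustering of
1 − TOM with a static height cut (0.99 default) — the "tree" variant
of dynamic cutting; the hybrid PAM refinement stage is intentionally
omitted at this scale. Clusters under 30 genes become grey; eigengenes
are the first principal component of the standardized module block,
unit sample variance, sign-fixed against the module mean profile; and
modules whose eigengene dissimilarity (1 − cor) falls below the merge
height (0.6) merge iteratively. Pearson correlation is used
throughout.

Module–trait association is the Pearson r (with two-sided p) of each
eigengene against per-sample trait values; constant traits are
reported missing. Hub screening keeps intramodular TOM edges above a
weight floor (default 0.2) and ranks genes by the sum of retained edge
weights, ties broken by identifier. On a 2,000-gene desk-scale panel
the intramodular TOM distribution tops out near 0.14, so the analysis
driver sets the floor at the same relative depth (0.05) — the 0.2
published floor presumes a much larger network.

## Integration, qPCR and enrichment

The evidence table joins three routes per gene: GWAS candidate window,
any DEG call (with upregulation specific to tolerant material tracked
separately: up in an NT contrast and not differentially expressed in
any NS contrast), and hub status. Candidates are called by a
configurable boolean rule over these flags; the default —
`(gwas AND deg) OR hub OR up-in-tolerant` — encodes the three routes
as a disjunction because no single formal criterion is standard.
Monotone rules never lose candidates when evidence is added.

qPCR quantification is the 2^−ΔΔCt method with amplification
efficiency fixed at 2: replicate Ct values are arithmetically averaged
per gene × condition before differencing, ΔCt is taken against the
reference gene (Actin), ΔΔCt against the control condition, so the
control RQ is 1 by construction. Concordance with RNA-seq is the
fraction of genes whose log2(RQ) agrees in sign with the RNA-seq
log2FC, plus the Pearson r of the two fold-change vectors.

Enrichment is the one-sided hypergeometric upper tail per term over a
user-supplied gene→term map, BH-adjusted; zero overlap gives p = 1 and
a term covering the background gives p = 1.

## Synthetic cohort generator

Every generator is a pure function of its seed.

**Genotypes.** Balding–Nichols drift: ancestral frequencies uniform on
the MAF range (0.05–0.5), subpopulation frequencies Beta-distributed
around them with drift parameter Fst (default 0.1, verified against an
independent Weir–Cockerham estimator), equal-sized subpopulations
(default 3, 201 lines), ancestry rows blended with a small admixture
fraction (0.1) so the structure matrix is informative but near-pure.
SNPs whose realized MAF falls outside the configured range are
redrawn. Markers are unlinked (linkage realism is out of scope).

**Phenotypes.** Six seedling traits (seedling/root length, shoot/root
fresh and dry weight) with realistic base means; normal-N values are
trait mean + causal-SNP effects (default 5 SNPs/trait) + a polygenic
line effect + replicate noise scaled so the genetic share of line-mean
variance equals the heritability (default 0.8). Low-N values multiply
the genetic value by the per-trait nitrogen effect (defaults 0.90,
0.93, 0.84, 0.89, 0.85, 0.93 — the published mean reductions) and a
line tolerance multiplier: archetypes at fixed fractions (10% tolerant
/ 75% intermediate / 15% sensitive) offset by ±archetype_separation
(default 0.08) and jittered by the genotype×nitrogen SD (0.02).
Tolerant lines therefore have low/normal ratios near 1, sensitive
below the population mean reduction. At the defaults the archetype
separation realizes ≈ 2.9 intermediate-class index SDs; recovery tests
use separation 0.10 with heritability 0.9 (≈ 4 SDs, asserted in-test)
so the ≥ 3-SD separation premise of the class-recovery benchmark
actually holds. Replicates are exchangeable; no batch effects.

**Counts.** 24 samples (NT/NS × leaf/root × two nitrogen levels × 3
replicates). Module genes load (0.7–1.0, random sign) on latent
per-sample factors that are orthogonalized across samples, so planted
modules remain distinguishable at 24 samples; gamma-Poisson
(negative-binomial) sampling with dispersion 0.1 around log-normal
base expression, log-normal library-size factors (SD 0.1) and mild
per-gene sample wobble (SD 0.25 log2) — both settable to zero for
distributional-limit checks. DE genes shift log2 means by ±de_log2fc
(default 2) between nitrogen levels within one material × tissue
contrast, with NS contrasts carrying three times the NT count
(mirroring the tolerant material's expression homeostasis), plus a
small set of core genes (default 4) responding in every contrast.

**qPCR.** Ct = 20 − log2(expression) + N(0, ct_sd) per well (the
baseline cancels in ΔΔCt), three biological × three technical
replicates, reference gene at fold change 1 by construction.

**What the generator does not emulate:** linkage maps and realistic LD
decay, batch effects, count outliers and heavy-tailed dispersions,
GC/length biases, shared polygenic architecture between the phenotype
and expression layers. Passing recovery tests therefore demonstrates
correctness of the estimators under their own model assumptions, not
robustness to every artifact of real field and sequencing data.

## Problem sizes

The test suite and acceptance script run at sizes chosen for a
single-CPU desk machine: null-scan calibration at 200 lines × 2,000
SNPs × 10 seeds; power at 200 × 1,000 × 50 seeds; DE calibration at
2,000 genes, 3 vs 3; module recovery at 5 × 50 genes × 24 samples × 10
seeds; classification recovery at 201 lines × 20 seeds. The analysis
drivers use a 201 × 5,000-SNP, 2,000-gene cohort. All numbers the
documentation quotes are produced by those runs.

## Known limitations

- D′ EM assumes Hardy–Weinberg within the pooled sample; inbred panels
  violate this, which is why r² (dosage-based) is the primary LD
  statistic.
- The static tree cut is cruder than the hybrid dynamic cut; on
  full-size data it tends to leave more genes grey and can split large
  modules (observed ARI ≈ 0.5 against planted labels on the full
  2,000-gene cohort vs ≈ 0.99 on the pure 250-gene benchmark).
- The scale-free fit criterion saturates at low powers on small panels;
  the analysis driver therefore builds the network at the study power
  (12) while still reporting the fit table.
- P3D holds variance components fixed across SNPs; for very large
  single-SNP effects this slightly deflates significance relative to
  exact per-SNP REML.
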