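# Methods

`mirepi` implements a three-stage analysis of shared common-variant
architecture between two disorders (an ASD-like and an epilepsy-like trait)
across miRNA-target gene sets, together with the synthetic-data generators
needed to exercise every stage at desk scale.

## 1. Gene-set construction

A structured evidence table (miRNA, condition, study, direction of
dysregulation) is filtered to miRNAs reported as dysregulated in **both**
conditions by at least two independent studies each. "In both conditions in
at least two independent studies" is read as >= 2 distinct studies *per
condition* (the replication reading); the threshold is a parameter.

Targets of the selected miRNAs are the genes that exceed a per-source score
cutoff in at least 4 of 5 prediction sources (DIANA, TargetScan, PicTar,
Miranda, miRDB) for at least one selected miRNA. Per-source cutoffs are
configuration; the default is each source's median supplied score, since
real per-source thresholds are database-version-specific and not portable.

Two refinements mirror the real pipeline: intersection with a
brain-expression membership list, and a top-25% haploinsufficiency filter.
The haploinsufficiency quantile is computed over the **full gene universe**,
not within the target set — the reported counts (313 of 23,476 genes) imply
a universe-level cutoff — and ties at the cutoff are retained. Genes without a
score are conservatively excluded from the top-quantile set.

Gene bodies become unmerged BED intervals (membership semantics, not
coverage); SNP membership uses the convention that a 0-based half-open
interval [a, b) contains 1-based position p iff a < p <= b. The 2x2
under-representation test is a Pearson chi-square without continuity
correction. Reconstructing the published counts (313 / 4,581 / 4,764 /
23,476) gives chi-square ~ 637.6, not the printed 402.95; the gene universe
behind the printed statistic is ambiguous (all coding vs brain-expressed), so
the package reports this value and never asserts it.

## 2. Genetic covariance

The estimand is the covariance rho_C of per-SNP standardized additive effects
between the two traits within a SNP partition C, with
rg_C = rho_C / sqrt(h2_1C h2_2C).

*LD scores.* ell_Cj sums bias-corrected squared genotype correlations
r2 - (1 - r2)/(n - 2) over partition-C SNPs within a 1,000-kb physical
window of SNP j (a stand-in for the 1-cM convention; there is no genetic map
at desk scale), including the self-pair when j is in C.

*Regression.* z1_j z2_j is regressed on the per-partition LD-score columns
plus a free intercept (the intercept absorbs sample overlap); the
coefficient on ell_C equals sqrt(N1 N2) rho_C / M_C. Heritabilities use the
univariate analogue (z^2 on the same design). Weights are a two-pass scheme:
an unweighted first pass estimates h2 and rho, then weights
1 / [(1 + N1 h1 ell/M)(1 + N2 h2 ell/M) + (sqrt(N1 N2) rho ell/M + icpt)^2]
are applied, following LD-score-regression practice. Standard errors come
from a delete-one block jackknife over 200 contiguous SNP blocks (default);
genetic correlations are jackknifed as ratios within the same loop, so the
genome-wide regression and the single-partition stratified fit are the same
computation and agree to machine precision.

Partitions must be disjoint; the general overlapping-annotation GLS
machinery of GNOVA-style estimators is out of scope. An important design
fact, discovered the hard way: if the partitions tile the entire SNP set and
LD scores barely vary, [1, ell_A, ell_B] is nearly collinear and the
intercept is unidentified — intergenic SNPs (present in any real gene
annotation) are what pin the intercept. The synthetic gene universe
therefore places genes over ~55% of the panel span by default.

*Empirical null.* The focal set's covariance is ranked against r (default
1,000) random same-size gene sets drawn without replacement from the
complement annotation, rebuilding the SNP partition per draw. The empirical
p uses add-one smoothing, (1 + #{draws <= observed}) / (r + 1), lower side
by default (the scientific hypothesis is negative covariance); a one-sided
t against the null draws is reported alongside, because both variants are in
published use for this comparison and they need not agree exactly. Draw-level fits reuse the full-data
weights (the total LD score does not depend on the draw) and skip the
jackknife; p can never be 0 and the seed is mandatory.

BH-FDR uses the standard step-up with monotonicity enforcement
(statsmodels), preserving input order.

## 3. Trio transmission

Clumping is the PLINK-style greedy procedure (defaults r2 >= 0.1 within
500 kb; ties on p broken by chrom, bp, SNP id). Scores are
sum(dosage x beta) over index SNPs below each p-value threshold
(5e-5, 1e-3, 0.01, 0.05, 0.1, 0.2), optionally restricted to a partition;
thresholds with zero surviving SNPs are flagged, never silently zero.

pTDT standardizes child-minus-midparent deviations by the midparent SD of
the **analyzed group** (subgroup analyses renormalize within subgroup; a
whole-sample option exists) and applies a one-sample t-test, two-sided by
default: published descriptions of the procedure are inconsistent on
sidedness (two-tailed in one place, one-sided in another), so the two-sided
default is the conservative reading and `alternative=` exposes the one-sided
mode. Degenerate all-zero deviations report mean 0, p = 1 by
convention. The best threshold minimizes the whole-sample pTDT p, ties going
to the smaller threshold.

The permutation test shuffles comorbidity labels preserving group sizes; the
statistic is the group mean deviation (well-defined for tiny groups),
computed from whole-sample-normalized deviations so the statistic is
exchangeable across permutations; p is add-one smoothed and directional in
the observed direction. The group contrast is Welch's t by default —
reconstructing the published group summaries matches the Welch statistic —
with a pooled-variance option, and Shapiro-Wilk / Bartlett diagnostics
reported alongside.

## 4. Synthetic data

*Panel.* Haplotypes are thresholded latent Gaussians: AR(1) with lag-one
correlation `within_block_r` inside each LD block, independent across
blocks; the per-SNP threshold is the normal quantile of a MAF drawn
uniformly from `maf_range` (default 0.05-0.5). This parametric model
replaces real reference LD so that pairwise expectations have closed forms
an independent Monte-Carlo oracle can verify. Alleles are random base pairs,
so a realistic fraction of SNPs is strand-ambiguous and exercised by the
harmonizer.

*Effects.* Standardized-genotype effects make h2 bookkeeping exact: within
partition C, (beta1, beta2) are bivariate normal with variances h2_tC / m_C
and covariance rho_C / m_C; heritability is allocated across partitions
proportionally to SNP count unless overridden. Default heritabilities in the
replicate studies are 0.20 and 0.15, near reported common-variant
heritabilities for the two disorders.

*GWAS.* Cohorts are resampled from the panel's haplotype pool; phenotypes
are genetic value plus N(0, 1 - h2) noise; every SNP is analyzed by
single-SNP least squares on dosage. Overlapping individuals with correlated
residuals generate a cross-trait intercept. Resampling from a finite pool of
2n haplotypes adds a uniform background-LD term ~ N h2 / (2n) to the mean
chi-square; it is absorbed by the free intercept and does not bias slopes
(the replicate studies confirm this empirically).

*Trios.* Parents are fresh draws from the haplotype pool; children inherit
one whole haplotype per parent with recombination only at block boundaries
(switch probability 0.5 per boundary, equivalent to an independent choice
per block), preserving within-block LD in offspring. Liability is genetic
value plus N(0, 1 - h2) residual, unit variance by construction, so
top-q ascertainment uses the exact normal quantile; rejection sampling has a
configurable candidate budget. Comorbidity labels come from a caller-supplied
rule on the liability components (the demo labels trios whose trait-2
liability exceeds its matching population quantile). Binary traits are never
simulated as case-control: the estimators consume z-scores, and
liability-scale covariance is what they target.

What the generator does **not** emulate: realistic human LD maps and
recombination, population structure and ancestry mixture, case-control
ascertainment of the discovery GWAS, imputation error (INFO is fixed at 1
for simulated SNPs; the QC filter is exercised by constructed tables), and
selection-induced parent-offspring correlation. Passing tests therefore
validate the estimators' logic and calibration under a clean polygenic
model, not their behavior under real-data pathologies.

## Replicate-study sizes

The operating-characteristic studies (also recomputed by
`scripts/acceptance.py`) use: sign recovery/CI coverage — m = 5,000 SNPs
(1,667 blocks of 3, r = 0.4), 500 panel individuals, n = 20,000 per trait,
rho_C = ±0.03, 50 replicates; Wald-null calibration — m = 1,000, n = 4,000,
200 replicates; gene-set-null calibration — 10 datasets x 10 exchangeable
focal draws, r = 200 draws; pTDT null — 500 trios x 100 replicates;
ascertainment power — top-10% liability, h2 = 0.5, 200 trios x 100
replicates. These are desk-scale versions of the analysis designs, chosen so
each estimator operates in its intended regime (hundreds of SNPs per
partition, jackknife blocks much smaller than the SNP count).

## Known limitations

- The LD-score window is physical, not genetic; LD scores and clumping use
  the same panel that generated the cohorts, so reference-mismatch noise is
  absent.
- The stratified model requires disjoint partitions and a free intercept;
  constrained-intercept modes are not implemented.
- With very small partitions (tens of SNPs) the per-partition covariance is
  noise-dominated; the demo analysis sizes its planted effect accordingly.
- The empirical gene-set null is slightly anti-conservative when the gene
  universe is tiny (draws can never contain the focal genes); at realistic
  gene counts the effect is negligible, and the calibration study uses the
  exchangeable design (focal drawn from the same pool as the null draws).
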