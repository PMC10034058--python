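# mirepi

Shared common-variant architecture between two disorders across miRNA-target
gene sets: annotation-partitioned genetic covariance with a random-gene-set
empirical null, and polygenic transmission disequilibrium testing (pTDT) in
parent-child trios — implemented as a tested, reusable pipeline and exercised
end to end on synthetic, LD-structured data.

## The problem

High clinical comorbidity between autism spectrum disorders (ASD) and
epilepsy is well explained by shared rare disrupting variation, but
genome-wide studies find no significant common-variant correlation between
them. A sharper question is whether *specific shared pathways* — here, the
target genes of miRNAs dysregulated in both conditions — carry a detectable
common-variant relationship. The analysis has three stages:

1. **Gene sets** — select miRNAs with replicated dysregulation in both
   disorders from a structured evidence table; form the consensus target set
   (genes predicted by >= 4 of 5 sources); refine by brain expression and
   top-25% haploinsufficiency; convert gene bodies to SNP partitions
   (miR / no_miR).
2. **Genetic covariance** — cross-trait LD-score regression: E[z1j z2j] =
   sqrt(N1 N2) Σ_C (rho_C / M_C) ℓ_Cj + intercept, with per-partition LD
   scores ℓ_Cj, block-jackknife SEs, genetic correlation
   rg_C = rho_C / sqrt(h2_1C h2_2C), BH-FDR across partitions, and an
   empirical null from 1,000 random same-size gene sets.
3. **Transmission** — LD-clumped, p-value-thresholded polygenic scores in
   trios; pTDT tests whether offspring scores deviate from the midparent
   mean ((child − midparent) / sd(midparent)); comorbidity-label permutations
   and a Welch contrast compare comorbid vs non-comorbid trios.

The real inputs (consortium GWAS, 1000 Genomes LD reference, a clinical trio
cohort) are not redistributable, so the package ships first-class simulators:
blockwise AR(1) thresholded-Gaussian reference panels, bivariate
partition-specific effects with exact heritability bookkeeping,
marginal-regression GWAS cohorts, and Mendelian trios with liability-threshold
ascertainment.

## Worked example

The demo analysis (`analysis/01_build_genesets.py` … `04_transmission.py`)
plants a negative genetic covariance (rho = −0.03) in the miR partition of a
2,400-SNP panel, simulates two GWAS of 20,000 individuals and 233 ascertained
trios (30 comorbid), and recovers the structure:

```
$ python analysis/03_genetic_covariance.py
1637 of 2400 SNPs survive harmonization + QC (strand-ambiguous pairs dropped)
       all: rho=-0.1978 (SE 0.3423), rg=-0.717, p=0.5633, FDR-p=0.6396
       miR: rho=-0.0174 (SE 0.0065), rg=-0.693, p=0.0077, FDR-p=0.0231
    no_miR: rho=-0.0078 (SE 0.0166), rg=-0.051, p=0.6396, FDR-p=0.6396
gene-set null: observed miR rho=-0.0174, 1000 draws mean -0.0021 (sd 0.0061),
empirical p=0.0090, one-sided t p=0.0061
```

The miR partition shows significant negative covariance (Wald p = 0.0077,
surviving FDR at 0.0231) and sits in the lower tail of 1,000 random gene-set
draws (empirical p = 0.009), while the genome-wide and no_miR estimates are
null — the partition-specific signal the method is designed to isolate.

```
$ python analysis/04_transmission.py
clumping: 1615 index SNPs from 1637
best threshold 0.2: whole-sample pTDT mean_dev=+0.2403, p=0.0002
    comorbid: n=30, mean_dev=+0.0139 (95% CI -0.4330, +0.4607), p=0.9499
 no_comorbid: n=203, mean_dev=+0.2678 (95% CI +0.1356, +0.4000), p=0.0001
10,000 label permutations: p_perm comorbid=0.9166, non-comorbid=0.0835
Welch contrast: t=-1.111 (df 34.7), p=0.2741
```

Trait-1 ascertainment produces the expected over-transmission of trait-1
risk alleles overall (+0.24 midparent-SD units, p = 2e-4), and trios
comorbid for the negatively-correlated second trait show visibly weaker
transmission (+0.01 vs +0.27) — the qualitative pattern the trio stage is
built to detect, though not significant at 30 comorbid trios.

## Layout

```
src/mirepi/          library: simulate/ (panel, effects, GWAS, trios),
                     genesets, sumstats, covariance, transmission, studies,
                     datasets, io
analysis/            numbered demo drivers (thin narratives over the library)
tests/               pytest suite incl. brute-force oracles and the
                     acceptance criteria
scripts/acceptance.py
```
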