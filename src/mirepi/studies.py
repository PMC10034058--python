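"""Replicate studies: parameter recovery, null calibration, and power.

Each function simulates its own data with the package generators and returns
summary statistics of the estimators' operating characteristics.  Study sizes
are desk-scale versions of the designs the estimators target: two gene-set
partitions plus intergenic background, SNP-heritabilities near reported
common-variant values for the two disorders (0.20 and 0.15), and partition
covariances of +/-0.03.  All functions are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from . import genesets as gs
from .covariance import geneset_null, ld_scores, ldsc_cross, stratified_covariance
from .simulate import draw_effects, make_reference_panel, simulate_sumstats, simulate_trios
from .transmission import permutation_test, ptdt, score

H2_TRAIT1 = 0.20  # ASD-like SNP heritability
H2_TRAIT2 = 0.15  # epilepsy-like SNP heritability


def _two_partition_setup(m_snps: int, n_genes: int, seed: int, snps_per_block=3,
                         within_block_r=0.4, n_individuals=500):
    """Panel + interleaved miR/no_miR gene partitions with intergenic gaps."""
    n_blocks = int(np.ceil(m_snps / snps_per_block))
    panel = make_reference_panel(
        n_individuals, n_blocks, snps_per_block, within_block_r, seed=seed
    )
    genes, coords = datasets.synthetic_gene_universe(n_genes, panel)
    bed_a, _ = gs.genes_to_bed(genes[0::2], coords)
    bed_b, _ = gs.genes_to_bed(genes[1::2], coords)
    ann = gs.snp_annotation({"miR": bed_a, "no_miR": bed_b}, panel)
    return panel, ann, genes, coords


@dataclass
class RecoveryStudy:
    n_replicates: int
    truth: dict
    estimates: pd.DataFrame
    sign_recovered: int  # replicates with both partition signs correct
    ci_covered: int      # 95% jackknife CIs covering truth (2 per replicate)
    n_cis: int


def recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    m_snps: int = 5000,
    n_gwas: int = 20_000,
    rho: float = 0.03,
) -> RecoveryStudy:
    """Stratified covariance on two-partition data with rho_C = +/-rho.

    Per replicate, fresh effects and fresh marginal-regression GWAS of
    ``n_gwas`` individuals per trait are drawn against a fixed reference
    panel; the study reports sign recovery and 95% jackknife CI coverage.
    """
    rng = np.random.default_rng(seed)
    panel, ann, _, _ = _two_partition_setup(m_snps, m_snps // 10, int(rng.integers(2**31)))
    ld = ld_scores(panel, ann)
    truth = {"miR": rho, "no_miR": -rho}
    rows, signs, cover = [], 0, 0
    for _ in range(n_replicates):
        eff = draw_effects(ann, H2_TRAIT1, H2_TRAIT2, truth, seed=int(rng.integers(2**31)))
        ss1, ss2 = simulate_sumstats(
            panel, eff, n_gwas, n_gwas, seed=int(rng.integers(2**31))
        )
        res = {r.partition: r for r in
               stratified_covariance(ss1, ss2, ld, ["miR", "no_miR"], n_blocks=200)}
        ok = all(np.sign(res[c].rho) == np.sign(truth[c]) for c in truth)
        signs += ok
        for c in truth:
            cover += abs(res[c].rho - truth[c]) < 1.96 * res[c].se_rho
            rows.append({"partition": c, "rho": res[c].rho, "se": res[c].se_rho})
    return RecoveryStudy(
        n_replicates, truth, pd.DataFrame(rows), signs, cover, 2 * n_replicates
    )


def wald_null_calibration(
    n_replicates: int = 200, seed: int = 0, m_snps: int = 1000, n_gwas: int = 4000
) -> dict:
    """Wald p-values for the miR partition under zero covariance everywhere.

    Returns the p-values and a KS test against U(0, 1).
    """
    rng = np.random.default_rng(seed)
    panel, ann, _, _ = _two_partition_setup(m_snps, m_snps // 10, int(rng.integers(2**31)))
    ld = ld_scores(panel, ann)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        eff = draw_effects(
            ann, H2_TRAIT1, H2_TRAIT2, {"miR": 0.0, "no_miR": 0.0},
            seed=int(rng.integers(2**31)),
        )
        ss1, ss2 = simulate_sumstats(
            panel, eff, n_gwas, n_gwas, seed=int(rng.integers(2**31))
        )
        res = stratified_covariance(ss1, ss2, ld, ["miR", "no_miR"], n_blocks=100)
        pvals[i] = res[0].p
    ks = stats.kstest(pvals, "uniform")
    return {"pvals": pvals, "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def geneset_null_calibration(
    n_repetitions: int = 100,
    r_draws: int = 200,
    seed: int = 0,
    n_datasets: int = 10,
    m_snps: int = 600,
    n_genes: int = 60,
    n_focal: int = 10,
    n_gwas: int = 8000,
    alpha: float = 0.05,
) -> dict:
    """Empirical-null p under exchangeability: the focal set is itself a
    random draw from the gene pool and the null draws come from that same
    pool, so observed and draws are iid given the data and p is uniform.
    """
    rng = np.random.default_rng(seed)
    reps_per_dataset = n_repetitions // n_datasets
    pvals = []
    for _ in range(n_datasets):
        panel, ann, genes, coords = _two_partition_setup(
            m_snps, n_genes, int(rng.integers(2**31)), n_individuals=400
        )
        full = gs.SnpAnnotation(
            ann.snp_ids,
            pd.DataFrame(
                {"genic": ann.membership.any(axis=1)},
                index=ann.membership.index,
            ),
        )
        eff = draw_effects(
            full, 0.3, 0.3, {"genic": 0.0}, seed=int(rng.integers(2**31))
        )
        ss1, ss2 = simulate_sumstats(
            panel, eff, n_gwas, n_gwas, seed=int(rng.integers(2**31))
        )
        universe = frozenset(genes)
        pool = gs.GeneSet("pool", universe, universe)
        for _ in range(reps_per_dataset):
            chosen = rng.choice(genes, size=n_focal, replace=False)
            focal = gs.GeneSet("focal", frozenset(chosen), universe)
            nd = geneset_null(
                ss1, ss2, panel, focal, pool, coords,
                r_draws=r_draws, seed=int(rng.integers(2**31)),
            )
            pvals.append(nd.p_empirical)
    pvals = np.array(pvals)
    return {
        "pvals": pvals,
        "rejection_rate": float(np.mean(pvals <= alpha)),
        "n": len(pvals),
    }


def _true_beta_sumstats(panel, eff) -> pd.DataFrame:
    """Discovery table carrying the generating effects (infinite-N limit)."""
    return pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "CHR": panel.chrom,
            "BP": panel.bp,
            "A1": panel.a1,
            "A2": panel.a2,
            "BETA": eff.beta1 / np.sqrt(2 * panel.maf * (1 - panel.maf)),
            "P": np.where(eff.beta1 != 0, 1e-8, 1.0),
        }
    )


def ptdt_null_calibration(
    n_replicates: int = 100, n_trios: int = 500, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Rejection rate of the one-sample pTDT test in unascertained trios."""
    rng = np.random.default_rng(seed)
    panel, ann, _, _ = _two_partition_setup(
        200, 20, int(rng.integers(2**31)), snps_per_block=5, n_individuals=400
    )
    eff = draw_effects(ann, 0.5, 0.0, {"miR": 0.0, "no_miR": 0.0},
                       seed=int(rng.integers(2**31)))
    ss = _true_beta_sumstats(panel, eff)
    rej = 0
    for _ in range(n_replicates):
        trios = simulate_trios(panel, eff, n_trios, seed=int(rng.integers(2**31)))
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        if ptdt(prs, trios).p_t < alpha:
            rej += 1
    return {"rejection_rate": rej / n_replicates, "n": n_replicates}


def ascertainment_power(
    n_replicates: int = 100, n_trios: int = 200, top_q: float = 0.1, seed: int = 0
) -> dict:
    """Fraction of replicates with positive mean trait-1 pTDT deviation under
    liability-top-q ascertainment of offspring (h2 = 0.5)."""
    rng = np.random.default_rng(seed)
    panel, ann, _, _ = _two_partition_setup(
        200, 20, int(rng.integers(2**31)), snps_per_block=5, n_individuals=400
    )
    eff = draw_effects(ann, 0.5, 0.0, {"miR": 0.0, "no_miR": 0.0},
                       seed=int(rng.integers(2**31)))
    ss = _true_beta_sumstats(panel, eff)
    positive = 0
    means = []
    for _ in range(n_replicates):
        trios = simulate_trios(
            panel, eff, n_trios, "liability_top_q", top_q,
            seed=int(rng.integers(2**31)),
        )
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        res = ptdt(prs, trios)
        means.append(res.mean_dev)
        positive += res.mean_dev > 0
    return {
        "positive_fraction": positive / n_replicates,
        "mean_deviation": float(np.mean(means)),
        "n": n_replicates,
    }


def planted_group_permutation(seed: int = 0, n_trios: int = 120, n_comorbid: int = 30,
                              n_perm: int = 1000) -> dict:
    """Permutation p for a planted under-transmission in the comorbid group."""
    rng = np.random.default_rng(seed)
    panel, ann, _, _ = _two_partition_setup(
        200, 20, int(rng.integers(2**31)), snps_per_block=5, n_individuals=400
    )
    eff = draw_effects(ann, 0.5, 0.0, {"miR": 0.0, "no_miR": 0.0},
                       seed=int(rng.integers(2**31)))
    ss = _true_beta_sumstats(panel, eff)
    trios = simulate_trios(panel, eff, n_trios, seed=int(rng.integers(2**31)))
    labels = np.zeros(n_trios, dtype=bool)
    labels[:n_comorbid] = True
    prs = score(trios, ss, set(ss["SNP"]), 1.0)
    mid_sd = np.std((prs.father[:, 0] + prs.mother[:, 0]) / 2, ddof=1)
    prs.child[labels, 0] -= 1.0 * mid_sd  # planted under-transmission
    p_comorbid, p_other = permutation_test(
        prs, trios, labels, n_perm=n_perm, seed=int(rng.integers(2**31))
    )
    return {"p_perm_comorbid": p_comorbid, "p_perm_other": p_other, "n": n_trios}


def reduction_identity_gap(seed: int = 0) -> dict:
    """Max |stratified(single whole-genome partition) - genome-wide cross
    regression| over (rho, se, h2_1, h2_2) on one simulated dataset."""
    rng = np.random.default_rng(seed)
    panel, ann, _, _ = _two_partition_setup(600, 60, int(rng.integers(2**31)))
    ld = ld_scores(panel, ann)
    eff = draw_effects(ann, H2_TRAIT1, H2_TRAIT2, {"miR": 0.02, "no_miR": -0.02},
                       seed=int(rng.integers(2**31)))
    ss1, ss2 = simulate_sumstats(panel, eff, 8000, 8000, seed=int(rng.integers(2**31)))
    cross = ldsc_cross(ss1, ss2, ld, n_blocks=50)
    strat = stratified_covariance(ss1, ss2, ld, ["all"], n_blocks=50)[0]
    gap = max(
        abs(cross.rho - strat.rho),
        abs(cross.se_rho - strat.se_rho),
        abs(cross.h2_1 - strat.h2_1),
        abs(cross.h2_2 - strat.h2_2),
    )
    return {"max_abs_gap": float(gap), "rho": cross.rho, "n": 600}
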