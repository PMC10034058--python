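"""Polygenic scoring in trios and the polygenic transmission disequilibrium test.

Discovery-GWAS effects are pruned by greedy LD clumping (most significant SNP
kept per correlated neighborhood), summed into per-individual polygenic scores
at a ladder of p-value thresholds, and compared between offspring and the
midparent expectation: under Mendelian transmission the child's expected score
is the parental average, so systematic deviations (standardized by the
midparent SD) indicate over- or under-transmission of trait-associated
alleles.  Comorbidity-label permutations and a Welch two-sample contrast
compare transmission between trio subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import SnpAnnotation
from .simulate.trios import TrioCohort

__all__ = [
    "PRSConfig",
    "PRSMatrix",
    "PTDTResult",
    "clump",
    "score",
    "score_thresholds",
    "ptdt",
    "select_best_threshold",
    "permutation_test",
    "compare_groups",
]

DEFAULT_THRESHOLDS = (5e-5, 0.001, 0.01, 0.05, 0.1, 0.2)


@dataclass
class PRSConfig:
    clump_r2: float = 0.1
    clump_kb: float = 500.0
    thresholds: tuple = DEFAULT_THRESHOLDS
    partition: str = "miR"

    def __post_init__(self):
        th = tuple(self.thresholds)
        if any(not 0 < t <= 1 for t in th) or any(
            b <= a for a, b in zip(th, th[1:])
        ):
            raise ValueError("thresholds must be strictly increasing in (0, 1]")
        self.thresholds = th


@dataclass
class PRSMatrix:
    """Scores per trio member per p-value threshold.

    ``father``/``mother``/``child`` are (n_trios, n_thresholds) arrays aligned
    with ``thresholds``; ``flagged`` marks thresholds where no SNP survived
    (their columns are NaN, never silently zero).
    """

    fam_ids: np.ndarray
    thresholds: tuple
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    n_snps: dict
    flagged: set = field(default_factory=set)

    def column(self, threshold: float) -> int:
        try:
            return self.thresholds.index(threshold)
        except ValueError:
            raise KeyError(f"threshold {threshold} not scored") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, mat in (("F", self.father), ("M", self.mother), ("C", self.child)):
            for i, fam in enumerate(self.fam_ids):
                rows.append([f"{fam}_{role}", role, fam, *mat[i]])
        return pd.DataFrame(
            rows, columns=["individual", "role", "fam", *map(str, self.thresholds)]
        )


@dataclass
class PTDTResult:
    group: str
    n_trios: int
    deviations: np.ndarray
    mean_dev: float
    ci95: tuple
    t_stat: float
    p_t: float
    threshold_used: float | None = None
    p_perm: float | None = None


# ---------------------------------------------------------------------------
# Clumping and scoring


def clump(
    ss: pd.DataFrame, panel, clump_r2: float = 0.1, clump_kb: float = 500.0
) -> list:
    """Greedy LD clumping: repeatedly take the unclaimed SNP with smallest p as
    an index SNP and claim all unclaimed SNPs within ``clump_kb`` with
    r^2 >= ``clump_r2`` to it.  Ties on p break by (chrom, bp, snp id).
    Returns the index-SNP ids in selection order.
    """
    if len(ss) == 0:
        return []
    snp_pos = {s: j for j, s in enumerate(np.asarray(panel.snp_ids, dtype=str))}
    df = ss[ss["SNP"].isin(snp_pos)].copy()
    if len(df) == 0:
        return []
    df["_j"] = df["SNP"].map(snp_pos)
    df = df.sort_values(["P", "CHR", "BP", "SNP"], kind="stable")

    X = panel.genotypes.astype(np.float64)
    X = X - X.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", X, X))
    norms[norms == 0] = np.inf
    Xn = X / norms

    bp = np.asarray(panel.bp, dtype=np.float64)
    chrom = np.asarray(panel.chrom, dtype=str)
    cand_j = df["_j"].to_numpy()
    claimed = np.zeros(panel.n_snps, dtype=bool)
    index_snps = []
    for j in cand_j:
        if claimed[j]:
            continue
        index_snps.append(str(panel.snp_ids[j]))
        near = (
            (chrom == chrom[j])
            & (np.abs(bp - bp[j]) <= clump_kb * 1000.0)
            & ~claimed
        )
        near_idx = np.flatnonzero(near)
        r = Xn[:, near_idx].T @ Xn[:, j]
        claimed[near_idx[r**2 >= clump_r2]] = True
        claimed[j] = True
    return index_snps


def _selected_snps(
    ss: pd.DataFrame,
    index_set,
    threshold: float,
    partition_annot: SnpAnnotation | None,
    partition: str | None,
) -> pd.DataFrame:
    sel = ss[ss["SNP"].isin(set(index_set)) & (ss["P"] < threshold)]
    if partition_annot is not None and partition is not None:
        mem = partition_annot.membership[partition]
        in_part = set(mem.index[mem])
        sel = sel[sel["SNP"].isin(in_part)]
    return sel


def score(
    trios: TrioCohort,
    ss: pd.DataFrame,
    index_set,
    threshold: float,
    partition_annot: SnpAnnotation | None = None,
    partition: str | None = None,
) -> PRSMatrix:
    """Polygenic scores at one threshold: sum of effect-allele dosage x BETA
    over index SNPs with p < threshold (optionally restricted to a partition),
    computed identically for father, mother, and child."""
    return score_thresholds(
        trios, ss, index_set, (threshold,), partition_annot, partition
    )


def score_thresholds(
    trios: TrioCohort,
    ss: pd.DataFrame,
    index_set,
    thresholds: Sequence[float],
    partition_annot: SnpAnnotation | None = None,
    partition: str | None = None,
) -> PRSMatrix:
    thresholds = tuple(thresholds)
    snp_pos = {s: j for j, s in enumerate(np.asarray(trios.snp_ids, dtype=str))}
    n_t = trios.n_trios
    shape = (n_t, len(thresholds))
    father = np.full(shape, np.nan)
    mother = np.full(shape, np.nan)
    child = np.full(shape, np.nan)
    n_snps = {}
    flagged = set()
    for k, th in enumerate(thresholds):
        sel = _selected_snps(ss, index_set, th, partition_annot, partition)
        sel = sel[sel["SNP"].isin(snp_pos)]
        n_snps[th] = len(sel)
        if len(sel) == 0:
            flagged.add(th)
            continue
        j = sel["SNP"].map(snp_pos).to_numpy()
        beta = sel["BETA"].to_numpy(float)
        father[:, k] = trios.father[:, j].astype(np.float64) @ beta
        mother[:, k] = trios.mother[:, j].astype(np.float64) @ beta
        child[:, k] = trios.child[:, j].astype(np.float64) @ beta
    return PRSMatrix(
        fam_ids=trios.fam_ids,
        thresholds=thresholds,
        father=father,
        mother=mother,
        child=child,
        n_snps=n_snps,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# pTDT


def _deviations(prs: PRSMatrix, k: int, rows: np.ndarray, sd: float | None = None):
    mid = (prs.father[rows, k] + prs.mother[rows, k]) / 2.0
    if sd is None:
        sd = float(np.std(mid, ddof=1))
    if sd == 0:
        raise ValueError("midparent scores have zero variance; deviations undefined")
    return (prs.child[rows, k] - mid) / sd


def ptdt(
    prs: PRSMatrix,
    trios: TrioCohort,
    group_mask: np.ndarray | None = None,
    threshold: float | None = None,
    group: str = "all",
    alternative: str = "two-sided",
) -> PTDTResult:
    """One-sample t-test of child-minus-midparent score deviations.

    Deviations are standardized by the midparent SD of the analyzed group.
    All-zero deviations (child score identically the midparent) are reported
    as mean 0 with p = 1 by convention rather than an undefined statistic.
    """
    if threshold is None:
        if len(prs.thresholds) != 1:
            raise ValueError("threshold required when the PRS matrix has several")
        threshold = prs.thresholds[0]
    k = prs.column(threshold)
    if threshold in prs.flagged:
        raise ValueError(f"threshold {threshold} has no surviving SNPs (flagged)")
    rows = (
        np.flatnonzero(np.asarray(group_mask, dtype=bool))
        if group_mask is not None
        else np.arange(prs.child.shape[0])
    )
    n = len(rows)
    if n < 3:
        raise ValueError("pTDT needs >= 3 trios in the group")
    dev = _deviations(prs, k, rows)
    mean = float(dev.mean())
    if np.allclose(dev, 0.0):
        return PTDTResult(group, n, dev, 0.0, (0.0, 0.0), 0.0, 1.0, threshold)
    res = stats.ttest_1samp(dev, 0.0, alternative=alternative)
    sem = dev.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    ci = (mean - tcrit * sem, mean + tcrit * sem)
    return PTDTResult(
        group, n, dev, mean, ci, float(res.statistic), float(res.pvalue), threshold
    )


def select_best_threshold(prs: PRSMatrix, trios: TrioCohort) -> float:
    """Threshold whose whole-sample pTDT p-value is smallest (ties -> smaller)."""
    usable = [t for t in prs.thresholds if t not in prs.flagged]
    if not usable:
        raise ValueError("every threshold column is flagged empty")
    best, best_p = None, np.inf
    for th in sorted(usable):
        p = ptdt(prs, trios, threshold=th).p_t
        if p < best_p:
            best, best_p = th, p
    return best


def permutation_test(
    prs: PRSMatrix,
    trios: TrioCohort,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    threshold: float | None = None,
) -> tuple:
    """Comorbidity-label permutation null for each group's mean pTDT deviation.

    Labels are permuted across trios preserving group sizes; the statistic is
    the group mean deviation (whole-sample midparent SD normalization so the
    statistic is exchangeable across permutations).  p = add-one-smoothed
    fraction of permuted statistics at least as extreme in the observed
    direction; never 0.
    """
    if seed is None:
        raise ValueError("seed is mandatory for a reproducible permutation test")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    if labels.sum() == 0 or labels.sum() == n:
        raise ValueError("both label groups must be non-empty")
    if threshold is None:
        if len(prs.thresholds) != 1:
            raise ValueError("threshold required when the PRS matrix has several")
        threshold = prs.thresholds[0]
    k = prs.column(threshold)
    dev = _deviations(prs, k, np.arange(n))

    rng = np.random.default_rng(seed)
    obs = np.array([dev[labels].mean(), dev[~labels].mean()])
    perm_stats = np.empty((n_perm, 2))
    for i in range(n_perm):
        lab = rng.permutation(labels)
        perm_stats[i, 0] = dev[lab].mean()
        perm_stats[i, 1] = dev[~lab].mean()
    p = np.empty(2)
    for g in range(2):
        if obs[g] < 0:
            extreme = perm_stats[:, g] <= obs[g]
        else:
            extreme = perm_stats[:, g] >= obs[g]
        p[g] = (1.0 + extreme.sum()) / (n_perm + 1.0)
    return float(p[0]), float(p[1])


def compare_groups(
    res_a: PTDTResult, res_b: PTDTResult, equal_var: bool = False
) -> dict:
    """Two-sample contrast of pTDT deviations between trio groups.

    Welch's unequal-variance t-test by default (pooled variance on request),
    with Shapiro-Wilk normality per group and Bartlett equality-of-variance
    diagnostics reported alongside.
    """
    a, b = np.asarray(res_a.deviations), np.asarray(res_b.deviations)
    if min(len(a), len(b)) < 2:
        raise ValueError("both groups need >= 2 trios")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return {
                "t": 0.0, "df": len(a) + len(b) - 2, "p": 1.0,
                "shapiro_a": None, "shapiro_b": None, "bartlett": None,
                "method": "degenerate (zero variance, equal means)",
            }
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
    else:
        sa, sb = va / len(a), vb / len(b)
        df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    diag = {
        "shapiro_a": stats.shapiro(a) if 3 <= len(a) <= 5000 else None,
        "shapiro_b": stats.shapiro(b) if 3 <= len(b) <= 5000 else None,
        "bartlett": stats.bartlett(a, b) if va > 0 and vb > 0 else None,
    }
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "method": "pooled" if equal_var else "welch",
        **diag,
    }


def welch_from_summaries(
    mean_a: float, se_a: float, n_a: int, mean_b: float, se_b: float, n_b: int
) -> tuple:
    """Welch t and df from group means and standard errors of the mean."""
    t = (mean_a - mean_b) / np.hypot(se_a, se_b)
    sa, sb = se_a**2, se_b**2
    df = (sa + sb) ** 2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
    return float(t), float(df)


def se_from_ci(half_width: float, n: int) -> float:
    """SEM implied by a 95% t confidence-interval half-width."""
    return float(half_width / stats.t.ppf(0.975, df=n - 1))
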