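"""Cross-trait LD-score regression and annotation-stratified genetic covariance.

The estimand is the covariance of per-SNP standardized additive effects
between two traits, aggregated over a SNP partition C (rho_C), together with
per-partition heritabilities and the genetic correlation
rg_C = rho_C / sqrt(h2_1C * h2_2C).  Estimation is method-of-moments: the
product z1_j * z2_j is regressed on per-partition LD scores with a free
intercept (which absorbs sample overlap), so that the coefficient on ell_C
equals sqrt(N1 N2) * rho_C / M_C.  Standard errors come from a delete-one
block jackknife over contiguous SNP blocks.  A random-gene-set resampling
null calibrates the focal partition's covariance against same-size draws from
the complement annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, SnpAnnotation

__all__ = [
    "LDScoreTable",
    "CovarianceResult",
    "NullDistribution",
    "ld_scores",
    "ldsc_cross",
    "stratified_covariance",
    "geneset_null",
    "fdr_adjust",
]


@dataclass
class LDScoreTable:
    """Per-SNP, per-partition LD scores plus partition SNP counts.

    ``ell`` is indexed by SNP id in panel order with one column per partition;
    the column "all" is always present and scores against every panel SNP.
    """

    snp: np.ndarray
    ell: pd.DataFrame
    m_by_partition: dict
    n_panel: int
    membership: pd.DataFrame | None = None

    @property
    def partitions(self) -> list:
        return [c for c in self.ell.columns if c != "all"]


@dataclass
class CovarianceResult:
    partition: str
    rho: float
    se_rho: float
    h2_1: float
    h2_2: float
    rg: float
    se_rg: float
    p: float
    intercept: float
    p_fdr: float | None = None
    rg_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "rho": self.rho,
            "se_rho": self.se_rho,
            "h2_1": self.h2_1,
            "h2_2": self.h2_2,
            "rg": self.rg,
            "se_rg": self.se_rg,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "intercept": self.intercept,
        }


@dataclass
class NullDistribution:
    observed: float
    draws: np.ndarray
    r: int
    side: str
    p_empirical: float
    p_t: float


# ---------------------------------------------------------------------------
# LD scores


def _standardized_panel(panel) -> np.ndarray:
    X = panel.genotypes.astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    sd[zero] = np.inf  # monomorphic column: correlation 0 with everything
    return (X - mu) / sd


def _banded_r2adj(panel, window_kb: float) -> np.ndarray:
    """Dense m x m bias-corrected squared-correlation matrix, zero outside the
    physical window / across chromosomes.  Intended for modest panel sizes."""
    n = panel.n_individuals
    if n < 3:
        raise ValueError("bias correction undefined for n < 3")
    X = _standardized_panel(panel)
    R = (X.T @ X) / n
    np.fill_diagonal(R, 1.0)  # self-pair exact, also for monomorphic columns
    r2 = R**2
    r2adj = r2 - (1.0 - r2) / (n - 2)
    bp = np.asarray(panel.bp, dtype=np.float64)
    chrom = np.asarray(panel.chrom, dtype=str)
    mask = (np.abs(bp[:, None] - bp[None, :]) <= window_kb * 1000.0) & (
        chrom[:, None] == chrom[None, :]
    )
    r2adj[~mask] = 0.0
    return r2adj


def ld_scores(
    panel, annotation: SnpAnnotation | None = None, window_kb: float = 1000.0
) -> LDScoreTable:
    """Per-partition LD scores ell_Cj = sum of r2_adj(j, k) over partition-C
    SNPs within ``window_kb`` of SNP j (same chromosome; self-pair included
    when j is in C), with r2_adj = r2 - (1 - r2) / (n - 2) computed on
    genotype dosages.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    n = panel.n_individuals
    if n < 3:
        raise ValueError("bias correction undefined for n < 3")
    m = panel.n_snps
    if annotation is not None:
        mem = annotation.membership.copy()
        if not np.array_equal(np.asarray(mem.index), np.asarray(panel.snp_ids)):
            raise ValueError("annotation SNPs do not match panel order")
    else:
        mem = pd.DataFrame(index=pd.Index(panel.snp_ids, name="SNP"))
    mem["all"] = True
    M = mem.to_numpy(dtype=np.float64)

    X = _standardized_panel(panel)
    bp = np.asarray(panel.bp, dtype=np.float64)
    chrom = np.asarray(panel.chrom, dtype=str)
    ell = np.zeros((m, M.shape[1]))
    chunk = 512
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        R = (X[:, a:b].T @ X) / n
        for j in range(a, b):
            R[j - a, j] = 1.0
        r2 = R**2
        r2adj = r2 - (1.0 - r2) / (n - 2)
        mask = (np.abs(bp[a:b, None] - bp[None, :]) <= window_kb * 1000.0) & (
            chrom[a:b, None] == chrom[None, :]
        )
        r2adj[~mask] = 0.0
        ell[a:b] = r2adj @ M
    ell_df = pd.DataFrame(ell, index=mem.index, columns=mem.columns)
    m_by = {c: int(mem[c].sum()) for c in mem.columns}
    return LDScoreTable(
        snp=np.asarray(panel.snp_ids),
        ell=ell_df,
        m_by_partition=m_by,
        n_panel=n,
        membership=mem.astype(bool),
    )


# ---------------------------------------------------------------------------
# Weighted regression with block jackknife


def _block_slices(m: int, n_blocks: int) -> list:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _wls_jackknife(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Full-sample WLS coefficients and delete-one-block jackknife replicates."""
    Xw = X * w[:, None]
    A = X.T @ Xw
    c = Xw.T @ y
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(f"collinear LD-score design (condition number {cond:.2g})")
    theta = np.linalg.solve(A, c)
    blocks = _block_slices(len(y), n_blocks)
    reps = np.empty((len(blocks), X.shape[1]))
    for i, sl in enumerate(blocks):
        Ab = X[sl].T @ Xw[sl]
        cb = Xw[sl].T @ y[sl]
        reps[i] = np.linalg.solve(A - Ab, c - cb)
    return theta, reps


def _jackknife_se(reps: np.ndarray) -> np.ndarray:
    B = reps.shape[0]
    return np.sqrt((B - 1) / B * np.sum((reps - reps.mean(axis=0)) ** 2, axis=0))


def _ensure_z(ss: pd.DataFrame) -> pd.DataFrame:
    if "Z" in ss.columns:
        return ss
    ss = ss.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ss["Z"] = np.where(ss["SE"] > 0, ss["BETA"] / ss["SE"], 0.0)
    return ss


def _align(ss1: pd.DataFrame, ss2: pd.DataFrame, ld: LDScoreTable):
    order = pd.Index(ld.ell.index)
    s1 = _ensure_z(ss1).set_index("SNP")
    s2 = _ensure_z(ss2).set_index("SNP")
    common = order.intersection(s1.index).intersection(s2.index)
    if len(common) == 0:
        raise ValueError("no SNPs shared between summary statistics and LD scores")
    common = order[order.isin(common)]  # panel order
    return s1.loc[common], s2.loc[common], ld.ell.loc[common]


def _fit_partitions(ss1, ss2, ld: LDScoreTable, cols: Sequence[str], n_blocks: int):
    s1, s2, ell = _align(ss1, ss2, ld)
    m = len(ell)
    if m < 2 * n_blocks:
        raise ValueError(f"{m} SNPs < 2 * {n_blocks} jackknife blocks")
    z1 = s1["Z"].to_numpy(float)
    z2 = s2["Z"].to_numpy(float)
    y12 = z1 * z2
    if not np.all(np.isfinite(y12)):
        raise ValueError("non-finite z-score products")
    n1 = float(s1["N"].mean())
    n2 = float(s2["N"].mean())
    M_all = ld.m_by_partition["all"]
    ell_tot = np.clip(ell["all"].to_numpy(float), 0.0, None)
    E = ell[list(cols)].to_numpy(float)
    X = np.column_stack([np.ones(m), E])
    M_C = np.array([ld.m_by_partition[c] for c in cols], dtype=float)

    # first pass: unweighted fits give the variance terms for the weights
    Xt = np.column_stack([np.ones(m), ell_tot])
    coef12, *_ = np.linalg.lstsq(Xt, y12, rcond=None)
    coef1, *_ = np.linalg.lstsq(Xt, z1**2, rcond=None)
    coef2, *_ = np.linalg.lstsq(Xt, z2**2, rcond=None)
    h1 = float(np.clip(coef1[1] * M_all / n1, 0.0, 1.0))
    h2 = float(np.clip(coef2[1] * M_all / n2, 0.0, 1.0))
    rho_tot = float(coef12[1] * M_all / np.sqrt(n1 * n2))
    icpt0 = float(coef12[0])

    v1 = 1.0 + n1 * h1 * ell_tot / M_all
    v2 = 1.0 + n2 * h2 * ell_tot / M_all
    c12 = np.sqrt(n1 * n2) * rho_tot * ell_tot / M_all + icpt0
    w12 = 1.0 / np.clip(v1 * v2 + c12**2, 1e-8, None)
    w1 = 1.0 / np.clip(v1**2, 1e-8, None)
    w2 = 1.0 / np.clip(v2**2, 1e-8, None)

    th12, rep12 = _wls_jackknife(X, y12, w12, n_blocks)
    th1, rep1 = _wls_jackknife(X, z1**2, w1, n_blocks)
    th2, rep2 = _wls_jackknife(X, z2**2, w2, n_blocks)

    scale_rho = M_C / np.sqrt(n1 * n2)
    rho = th12[1:] * scale_rho
    rho_reps = rep12[:, 1:] * scale_rho
    h2_1 = th1[1:] * M_C / n1
    h2_2 = th2[1:] * M_C / n2
    h1_reps = rep1[:, 1:] * M_C / n1
    h2_reps = rep2[:, 1:] * M_C / n2
    return {
        "cols": list(cols),
        "rho": rho,
        "rho_reps": rho_reps,
        "h2_1": h2_1,
        "h2_2": h2_2,
        "h1_reps": h1_reps,
        "h2_reps": h2_reps,
        "intercept": float(th12[0]),
    }


def _results_from_fit(fit: dict) -> list:
    out = []
    se_rho = _jackknife_se(fit["rho_reps"])
    for k, name in enumerate(fit["cols"]):
        rho = float(fit["rho"][k])
        se = float(se_rho[k])
        h1 = float(fit["h2_1"][k])
        h2 = float(fit["h2_2"][k])
        defined = h1 > 0 and h2 > 0
        rg = rho / np.sqrt(h1 * h2) if defined else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            rg_reps = np.where(
                (fit["h1_reps"][:, k] > 0) & (fit["h2_reps"][:, k] > 0),
                fit["rho_reps"][:, k]
                / np.sqrt(np.abs(fit["h1_reps"][:, k] * fit["h2_reps"][:, k])),
                np.nan,
            )
        se_rg = (
            float(_jackknife_se(rg_reps[None].T).item())
            if defined and not np.isnan(rg_reps).any()
            else np.nan
        )
        p = float(2.0 * norm.sf(abs(rho / se))) if se > 0 else np.nan
        out.append(
            CovarianceResult(
                partition=name,
                rho=rho,
                se_rho=se,
                h2_1=h1,
                h2_2=h2,
                rg=float(rg),
                se_rg=se_rg,
                p=p,
                intercept=fit["intercept"],
                rg_defined=defined,
            )
        )
    return out


def ldsc_cross(
    ss1: pd.DataFrame, ss2: pd.DataFrame, ld: LDScoreTable, n_blocks: int = 200
) -> CovarianceResult:
    """Genome-wide cross-trait LD-score regression.

    Weighted least squares of z1*z2 on the genome-wide LD score with a free
    intercept; the slope is rescaled to the covariance scale
    rho = slope * M / sqrt(N1 * N2), heritabilities come from the univariate
    analogue (z^2 on ell), and SEs from a block jackknife.
    """
    fit = _fit_partitions(ss1, ss2, ld, ["all"], n_blocks)
    return _results_from_fit(fit)[0]


def stratified_covariance(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ld: LDScoreTable,
    partitions: Sequence[str],
    n_blocks: int = 200,
) -> list:
    """Per-partition genetic covariance by multiple regression of z1*z2 on the
    per-partition LD-score columns plus a free intercept.  Partitions must be
    disjoint SNP sets present in the LD-score table.
    """
    missing = set(partitions) - set(ld.ell.columns)
    if missing:
        raise ValueError(f"partitions absent from LD scores: {sorted(missing)}")
    if ld.membership is not None and len(partitions) > 1:
        overlap = ld.membership[list(partitions)].sum(axis=1) > 1
        if overlap.any():
            raise ValueError(
                f"partitions overlap on {int(overlap.sum())} SNP(s); disjoint sets required"
            )
    fit = _fit_partitions(ss1, ss2, ld, list(partitions), n_blocks)
    return _results_from_fit(fit)


# ---------------------------------------------------------------------------
# Random-gene-set empirical null


def _gene_snp_indices(genes, coords: Mapping, panel) -> dict:
    bp = np.asarray(panel.bp)
    chrom = np.asarray(panel.chrom, dtype=str)
    out = {}
    for g in genes:
        c, a, b = coords[g]
        out[g] = np.flatnonzero((chrom == str(c)) & (bp > a) & (bp <= b))
    return out


def geneset_null(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    panel,
    focal_set: GeneSet,
    complement_pool: GeneSet,
    coords: Mapping,
    r_draws: int = 1000,
    seed: int | None = None,
    side: str = "lower",
    window_kb: float = 1000.0,
) -> NullDistribution:
    """Empirical null for the focal gene set's covariance from random same-size
    gene sets drawn without replacement from the complement pool.

    Each draw rebuilds the SNP partition (drawn genes vs remaining pool genes),
    recomputes the stratified point estimate for that partition, and the
    empirical p is the add-one-smoothed rank of the observed covariance
    (default lower side, matching a negative-covariance hypothesis).
    """
    if seed is None:
        raise ValueError("seed is mandatory for a reproducible resampling null")
    if r_draws < 1:
        raise ValueError("r_draws must be >= 1")
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    pool = sorted(complement_pool.genes)
    k = len(focal_set.genes)
    if len(pool) < k:
        raise ValueError("complement pool smaller than focal set")

    rng = np.random.default_rng(seed)
    genes = sorted(set(pool) | set(focal_set.genes))
    gene_idx = _gene_snp_indices(genes, coords, panel)
    S = _banded_r2adj(panel, window_kb)
    m = panel.n_snps

    union_mask = np.zeros(m, dtype=bool)
    for g in genes:
        union_mask[gene_idx[g]] = True
    ell_all = S.sum(axis=1)

    s1 = _ensure_z(ss1).set_index("SNP")
    s2 = _ensure_z(ss2).set_index("SNP")
    snp_index = pd.Index(np.asarray(panel.snp_ids, dtype=str))
    present = snp_index.isin(s1.index) & snp_index.isin(s2.index)
    rows = np.flatnonzero(present)
    ids = snp_index[rows]
    z1 = s1.loc[ids, "Z"].to_numpy(float)
    z2 = s2.loc[ids, "Z"].to_numpy(float)
    y = z1 * z2
    n1 = float(s1.loc[ids, "N"].mean())
    n2 = float(s2.loc[ids, "N"].mean())

    # weights: fixed across draws (the total LD score does not depend on the draw)
    ell_tot = np.clip(ell_all[rows], 0.0, None)
    Xt = np.column_stack([np.ones(len(rows)), ell_tot])
    coef12, *_ = np.linalg.lstsq(Xt, y, rcond=None)
    coef1, *_ = np.linalg.lstsq(Xt, z1**2, rcond=None)
    coef2, *_ = np.linalg.lstsq(Xt, z2**2, rcond=None)
    h1 = float(np.clip(coef1[1] * m / n1, 0.0, 1.0))
    h2 = float(np.clip(coef2[1] * m / n2, 0.0, 1.0))
    v1 = 1.0 + n1 * h1 * ell_tot / m
    v2 = 1.0 + n2 * h2 * ell_tot / m
    c12 = coef12[1] * ell_tot + coef12[0]
    w = 1.0 / np.clip(v1 * v2 + c12**2, 1e-8, None)

    def rho_of(mask_focal: np.ndarray) -> float:
        mask_rest = union_mask & ~mask_focal
        ell_f = S[:, mask_focal].sum(axis=1)[rows]
        ell_r = S[:, mask_rest].sum(axis=1)[rows]
        X = np.column_stack([np.ones(len(rows)), ell_f, ell_r])
        Xw = X * w[:, None]
        theta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        M_f = int(mask_focal.sum())
        return float(theta[1] * M_f / np.sqrt(n1 * n2))

    focal_mask = np.zeros(m, dtype=bool)
    for g in focal_set.genes:
        focal_mask[gene_idx[g]] = True
    observed = rho_of(focal_mask)

    draws = np.empty(r_draws)
    pool_arr = np.array(pool, dtype=object)
    for i in range(r_draws):
        chosen = rng.choice(pool_arr, size=k, replace=False)
        mask = np.zeros(m, dtype=bool)
        for g in chosen:
            mask[gene_idx[g]] = True
        draws[i] = rho_of(mask)

    if side == "lower":
        p_emp = (1.0 + np.sum(draws <= observed)) / (r_draws + 1.0)
        tt = (observed - draws.mean()) / draws.std(ddof=1)
        p_t = float(t_dist.cdf(tt, df=r_draws - 1))
    else:
        p_emp = (1.0 + np.sum(draws >= observed)) / (r_draws + 1.0)
        tt = (observed - draws.mean()) / draws.std(ddof=1)
        p_t = float(t_dist.sf(tt, df=r_draws - 1))
    return NullDistribution(observed, draws, r_draws, side, float(p_emp), p_t)


# ---------------------------------------------------------------------------
# Multiple testing


def fdr_adjust(pvalues: Mapping[str, float]) -> dict:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    names = list(pvalues)
    p = np.array([pvalues[n] for n in names], dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = multipletests(p, method="fdr_bh")[1]
    return dict(zip(names, adj))
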