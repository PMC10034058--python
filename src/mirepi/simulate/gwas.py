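"""Marginal-regression GWAS summary statistics from simulated cohorts.

Cohorts are resampled from the panel's haplotype pool (two haplotypes per
individual, with replacement), phenotypes are genetic value plus Gaussian
noise of variance 1 - h2, and each SNP is analyzed by single-SNP least squares
on allele dosage — the estimator real GWAS consortia report.  A shared block
of individuals between the two cohorts, with correlated residuals, emulates
sample overlap and feeds the cross-trait regression intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import EffectTable
from .panel import ReferencePanel

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "FRQ", "INFO"]

_CHUNK = 1024


def _marginal_ols(X: np.ndarray, y: np.ndarray) -> tuple:
    """Per-SNP slope, SE, and allele frequency from single-SNP regressions."""
    n, m = X.shape
    yc = (y - y.mean()).astype(np.float64)
    Syy = float(yc @ yc)
    beta = np.empty(m)
    se = np.empty(m)
    frq = np.empty(m)
    for a in range(0, m, _CHUNK):
        b = min(a + _CHUNK, m)
        Xc = X[:, a:b].astype(np.float32)
        mu = Xc.mean(axis=0)
        Xc -= mu
        Sxx = np.einsum("ij,ij->j", Xc, Xc, dtype=np.float64)
        Sxy = Xc.T.astype(np.float64) @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            bh = np.where(Sxx > 0, Sxy / np.where(Sxx > 0, Sxx, 1.0), 0.0)
            sigma2 = np.clip((Syy - bh * Sxy) / (n - 2), 0.0, None)
            s = np.where(Sxx > 0, np.sqrt(sigma2 / np.where(Sxx > 0, Sxx, 1.0)), np.inf)
        beta[a:b] = bh
        se[a:b] = s
        frq[a:b] = mu / 2.0
    return beta, se, frq


def _genetic_values(X: np.ndarray, panel: ReferencePanel, beta: np.ndarray) -> np.ndarray:
    """X_std @ beta with standardization by the panel's generating maf."""
    n, m = X.shape
    g = np.zeros(n, dtype=np.float64)
    p = panel.maf
    scale = (beta / np.sqrt(2 * p * (1 - p))).astype(np.float64)
    offset = float(np.sum(2 * p * scale))
    for a in range(0, m, _CHUNK):
        b = min(a + _CHUNK, m)
        g += X[:, a:b].astype(np.float32) @ scale[a:b]
    return g - offset


def _to_frame(panel: ReferencePanel, beta, se, frq, n: int) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "CHR": panel.chrom,
            "BP": panel.bp,
            "A1": panel.a1,
            "A2": panel.a2,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
            "FRQ": frq,
            "INFO": 1.0,
        }
    )


def simulate_sumstats(
    panel: ReferencePanel,
    effects: EffectTable,
    n1: int,
    n2: int,
    n_overlap: int = 0,
    resid_corr: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two GWAS summary-statistic tables with optional sample overlap.

    The first ``n_overlap`` individuals are shared between cohorts and their
    residuals correlate at ``resid_corr``; with full overlap and correlated
    residuals the cross-trait regression intercept becomes non-zero while the
    slope still targets the genetic covariance.
    """
    if min(n1, n2) < 10:
        raise ValueError("sample sizes < 10: marginal regression degenerate")
    if not 0 <= n_overlap <= min(n1, n2):
        raise ValueError("n_overlap must be <= min(n1, n2)")
    if abs(resid_corr) > 1:
        raise ValueError("|resid_corr| must be <= 1")

    rng = np.random.default_rng(seed)
    n_hap = panel.haplotypes.shape[0]
    idx1 = rng.integers(0, n_hap, size=(n1, 2))
    idx2 = rng.integers(0, n_hap, size=(n2, 2))
    idx2[:n_overlap] = idx1[:n_overlap]

    u1 = rng.standard_normal(n1)
    u2 = rng.standard_normal(n2)
    u2[:n_overlap] = resid_corr * u1[:n_overlap] + np.sqrt(
        max(0.0, 1.0 - resid_corr**2)
    ) * u2[:n_overlap]

    out = []
    for idx, u, beta, h2, n in (
        (idx1, u1, effects.beta1, effects.h2_1, n1),
        (idx2, u2, effects.beta2, effects.h2_2, n2),
    ):
        X = panel.haplotypes[idx[:, 0]].astype(np.int8) + panel.haplotypes[idx[:, 1]]
        y = _genetic_values(X, panel, beta) + np.sqrt(max(0.0, 1.0 - h2)) * u
        bh, se, frq = _marginal_ols(X, y)
        out.append(_to_frame(panel, bh, se, frq, n))
        del X
    return out[0], out[1]
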