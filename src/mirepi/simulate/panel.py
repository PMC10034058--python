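"""Blockwise AR(1) latent-Gaussian reference panels.

Haplotype alleles are obtained by thresholding a latent Gaussian process that
is AR(1)-correlated within LD blocks and independent across blocks; the
per-SNP threshold is the normal quantile of the requested allele frequency.
This parametric LD model replaces a real reference panel at desk scale: its
closed-form pairwise structure lets tests check LD summaries against
independent Monte-Carlo estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

_BASES = np.array(list("ACGT"))


@dataclass
class ReferencePanel:
    """Phased genotype reference panel with known block-LD structure.

    Positions ``bp`` are 1-based and strictly increasing within a chromosome.
    ``haplotypes`` is (2 * n_individuals, m) of {0,1} minor-allele indicators;
    row pairs (2i, 2i+1) belong to individual i.  ``a1`` is the minor (counted)
    allele, ``a2`` the other allele.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    maf: np.ndarray
    haplotypes: np.ndarray
    block_index: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    within_block_r: float = 0.0

    _genotypes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def genotypes(self) -> np.ndarray:
        """n_individuals x m minor-allele dosages, the sum of each row pair."""
        if self._genotypes is None:
            self._genotypes = (
                self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2]
            )
        return self._genotypes

    @property
    def observed_frq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def standardized_genotypes(self, dtype=np.float32) -> np.ndarray:
        """Genotypes centred and scaled by sqrt(2 p (1-p)) with p = requested maf."""
        p = self.maf
        return ((self.genotypes - 2 * p) / np.sqrt(2 * p * (1 - p))).astype(dtype)


def _ar1_latent(rng, n_rows: int, n_cols: int, r: float) -> np.ndarray:
    z = rng.standard_normal((n_rows, n_cols))
    if r > 0:
        c = np.sqrt(1.0 - r * r)
        for j in range(1, n_cols):
            z[:, j] = r * z[:, j - 1] + c * z[:, j]
    return z


def make_reference_panel(
    n_individuals: int,
    n_blocks: int,
    snps_per_block: int,
    within_block_r: float = 0.0,
    maf_range: tuple = (0.05, 0.5),
    seed: int | None = None,
    chrom: str = "1",
    bp_spacing: int = 10_000,
) -> ReferencePanel:
    """Simulate a phased reference panel of ``n_blocks`` independent LD blocks.

    Within a block, latent Gaussians follow an AR(1) with lag-one correlation
    ``within_block_r``; alleles are 1 where the latent value falls below the
    normal quantile of the SNP's allele frequency (drawn uniformly from
    ``maf_range``).  Deterministic given ``seed``.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if n_blocks < 1 or snps_per_block < 1:
        raise ValueError("n_blocks and snps_per_block must be positive")
    if not 0.0 <= within_block_r < 1.0:
        raise ValueError("within_block_r must be in [0, 1); r = 1 is degenerate LD")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")

    rng = np.random.default_rng(seed)
    m = n_blocks * snps_per_block
    maf = rng.uniform(lo, hi, size=m)
    tau = norm.ppf(maf)

    hap = np.empty((2 * n_individuals, m), dtype=np.int8)
    for b in range(n_blocks):
        sl = slice(b * snps_per_block, (b + 1) * snps_per_block)
        z = _ar1_latent(rng, 2 * n_individuals, snps_per_block, within_block_r)
        hap[:, sl] = z < tau[sl]

    a2 = rng.choice(_BASES, size=m)
    shift = rng.integers(1, 4, size=m)  # any of the 3 other bases, ambiguous pairs allowed
    a1 = _BASES[(np.searchsorted(_BASES, a2) + shift) % 4]

    return ReferencePanel(
        snp_ids=np.array([f"rs{i + 1}" for i in range(m)], dtype=object),
        chrom=np.full(m, str(chrom), dtype=object),
        bp=np.arange(1, m + 1, dtype=np.int64) * bp_spacing,
        maf=maf,
        haplotypes=hap,
        block_index=np.repeat(np.arange(n_blocks), snps_per_block),
        a1=a1,
        a2=a2,
        within_block_r=float(within_block_r),
    )
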