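"""Bivariate per-SNP genetic effects with partition-specific covariance.

Effects are on the standardized-genotype scale (each SNP contributes variance
beta^2), so heritability and covariance bookkeeping is exact: a partition C
with m_C SNPs allocated heritability h2_tC and covariance rho_C draws each
SNP's (beta1, beta2) from a bivariate normal with variances h2_tC / m_C and
covariance rho_C / m_C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ..genesets import SnpAnnotation


@dataclass
class EffectTable:
    """Per-SNP standardized effects for two traits plus the generating targets."""

    snp_ids: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    partition_of_snp: np.ndarray
    h2_1: float
    h2_2: float
    cov_by_partition: dict

    @property
    def n_snps(self) -> int:
        return len(self.beta1)

    def partition_covariance(self, name: str) -> float:
        """Realized sum over partition SNPs of beta1*beta2 (not the target)."""
        m = self.partition_of_snp == name
        return float(np.sum(self.beta1[m] * self.beta2[m]))


def draw_effects(
    annotation: SnpAnnotation,
    h2_1: float,
    h2_2: float,
    cov_by_partition: Mapping[str, float],
    seed: int | None = None,
    h2_share: Mapping[str, float] | None = None,
) -> EffectTable:
    """Draw per-SNP bivariate-normal effects with partition-specific covariance.

    Heritability is allocated across the partitions named in
    ``cov_by_partition`` proportionally to SNP count, unless ``h2_share`` maps
    partition -> fraction of total h2.  SNPs outside all named partitions get
    zero effects.  The 2x2 per-partition covariance matrix must be positive
    semidefinite: |rho_C| <= sqrt(h2_1C * h2_2C).
    """
    for t, h2 in (("h2_1", h2_1), ("h2_2", h2_2)):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"{t} must be in [0, 1]")
    parts = list(cov_by_partition)
    missing = set(parts) - set(annotation.partitions)
    if missing:
        raise ValueError(f"partitions absent from annotation: {sorted(missing)}")
    if not annotation.is_disjoint(parts):
        raise ValueError("effect partitions must be disjoint")

    m_by = {c: int(annotation.mask(c).sum()) for c in parts}
    m_total = sum(m_by.values())
    if m_total == 0:
        raise ValueError("no SNPs in any effect partition")
    if h2_share is None:
        share = {c: m_by[c] / m_total for c in parts}
    else:
        share = {c: float(h2_share[c]) for c in parts}
        s = sum(share.values())
        if not np.isclose(s, 1.0):
            raise ValueError(f"h2_share must sum to 1 (got {s})")

    rng = np.random.default_rng(seed)
    m = annotation.n_snps
    beta = np.zeros((m, 2))
    labels = np.full(m, "none", dtype=object)
    for c in parts:
        mask = annotation.mask(c)
        labels[mask] = c
        m_c = m_by[c]
        if m_c == 0:
            continue
        v1 = h2_1 * share[c] / m_c
        v2 = h2_2 * share[c] / m_c
        cv = cov_by_partition[c] / m_c
        if cv * cv > v1 * v2 + 1e-15:
            raise ValueError(
                f"partition {c!r}: |cov| {abs(cov_by_partition[c]):g} exceeds "
                f"sqrt(h2_1C * h2_2C) = {np.sqrt(v1 * v2) * m_c:g}"
            )
        cov = np.array([[v1, cv], [cv, v2]])
        # eigen construction tolerates the semidefinite boundary (|rho| at max)
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        root = v @ np.diag(np.sqrt(w))
        beta[mask] = rng.standard_normal((m_c, 2)) @ root.T

    return EffectTable(
        snp_ids=np.asarray(annotation.snp_ids),
        beta1=beta[:, 0],
        beta2=beta[:, 1],
        partition_of_snp=labels,
        h2_1=float(h2_1),
        h2_2=float(h2_2),
        cov_by_partition=dict(cov_by_partition),
    )
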