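"""Mendelian trio cohorts with optional liability-threshold ascertainment.

Parents are fresh individuals drawn from the panel's haplotype pool; each
child receives one recombined haplotype per parent, with crossovers only at
LD-block boundaries (switch probability 0.5 per boundary, i.e. blocks are
transmitted intact and independently).  Offspring can be ascertained on the
trait-1 liability (genetic value plus residual) exceeding a population
quantile, emulating clinical recruitment of affected probands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import EffectTable
from .panel import ReferencePanel


@dataclass
class TrioCohort:
    """Aligned father/mother/child dosage matrices plus per-trio labels."""

    fam_ids: np.ndarray
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    comorbid: np.ndarray
    liability: np.ndarray
    components: pd.DataFrame
    snp_ids: np.ndarray

    @property
    def n_trios(self) -> int:
        return self.child.shape[0]

    @property
    def n_snps(self) -> int:
        return self.child.shape[1]


def mendelian_consistent(trios: TrioCohort) -> np.ndarray:
    """Boolean (n_trios, n_snps): child dosage reachable from parental dosages."""
    f, m, c = trios.father, trios.mother, trios.child
    lo = (f == 2).astype(np.int8) + (m == 2)
    hi = (f >= 1).astype(np.int8) + (m >= 1)
    return (c >= lo) & (c <= hi)


def _std_scale(panel: ReferencePanel, beta: np.ndarray) -> tuple:
    p = panel.maf
    w = beta / np.sqrt(2 * p * (1 - p))
    return w.astype(np.float64), float(np.sum(2 * p * w))


def _genetic(G: np.ndarray, w: np.ndarray, offset: float) -> np.ndarray:
    return G.astype(np.float32) @ w - offset


def _transmit(rng, hap_a: np.ndarray, hap_b: np.ndarray, block_index: np.ndarray):
    """One gamete per row: per LD block, copy the block from hap_a or hap_b."""
    n_blocks = int(block_index.max()) + 1
    choice = rng.integers(0, 2, size=(hap_a.shape[0], n_blocks))
    pick = choice[:, block_index].astype(bool)
    return np.where(pick, hap_b, hap_a)


def simulate_trios(
    panel: ReferencePanel,
    effects: EffectTable,
    n_trios: int,
    ascertainment: str = "none",
    top_q: float = 1.0,
    seed: int | None = None,
    comorbid_rule: Callable[[pd.DataFrame], np.ndarray] | None = None,
    max_candidates: int | None = None,
) -> TrioCohort:
    """Simulate ``n_trios`` parent-child trios, optionally liability-ascertained.

    Under ``ascertainment="liability_top_q"`` candidate trios are generated and
    kept only when the child's trait-1 liability exceeds the population
    (1 - top_q) quantile (the liability scale has unit variance by
    construction, so the normal quantile is exact).  ``comorbid_rule`` maps the
    per-trio component table to a boolean comorbidity label.
    """
    if ascertainment not in ("none", "liability_top_q"):
        raise ValueError(f"unknown ascertainment {ascertainment!r}")
    if not 0.0 < top_q <= 1.0:
        raise ValueError("top_q must be in (0, 1]")
    if n_trios < 1:
        raise ValueError("n_trios must be positive")
    rng = np.random.default_rng(seed)
    H = panel.haplotypes
    n_hap = H.shape[0]
    block_index = panel.block_index

    w1, off1 = _std_scale(panel, effects.beta1)
    w2, off2 = _std_scale(panel, effects.beta2)
    s1 = np.sqrt(max(0.0, 1.0 - effects.h2_1))
    s2 = np.sqrt(max(0.0, 1.0 - effects.h2_2))

    select = ascertainment == "liability_top_q" and top_q < 1.0
    thresh = norm.ppf(1.0 - top_q) if select else -np.inf
    if max_candidates is None:
        max_candidates = max(10_000, 1_000 * n_trios)

    kept: list = []
    n_kept = 0
    n_seen = 0
    while n_kept < n_trios:
        batch = n_trios - n_kept
        if select:
            batch = int(np.ceil(batch / top_q * 1.3)) + 16
        if n_seen + batch > max_candidates:
            batch = max_candidates - n_seen
            if batch <= 0:
                raise RuntimeError(
                    f"ascertainment attempt budget exhausted: kept {n_kept}/{n_trios} "
                    f"after {n_seen} candidates (top_q={top_q})"
                )
        n_seen += batch

        fi = rng.integers(0, n_hap, size=(batch, 2))
        mi = rng.integers(0, n_hap, size=(batch, 2))
        fa = H[fi[:, 0]]
        fb = H[fi[:, 1]]
        ma = H[mi[:, 0]]
        mb = H[mi[:, 1]]
        gam_f = _transmit(rng, fa, fb, block_index)
        gam_m = _transmit(rng, ma, mb, block_index)
        child = (gam_f + gam_m).astype(np.int8)
        father = (fa.astype(np.int8) + fb).astype(np.int8)
        mother = (ma.astype(np.int8) + mb).astype(np.int8)

        g1 = _genetic(child, w1, off1)
        g2 = _genetic(child, w2, off2)
        r1 = rng.standard_normal(batch)
        r2 = rng.standard_normal(batch)
        lia1 = g1 + s1 * r1
        lia2 = g2 + s2 * r2

        keep = lia1 > thresh if select else np.ones(batch, dtype=bool)
        if not keep.any():
            continue
        comp = pd.DataFrame(
            {
                "g1_child": g1[keep],
                "g2_child": g2[keep],
                "g1_father": _genetic(father[keep], w1, off1),
                "g1_mother": _genetic(mother[keep], w1, off1),
                "g2_father": _genetic(father[keep], w2, off2),
                "g2_mother": _genetic(mother[keep], w2, off2),
                "resid1": r1[keep] * s1,
                "resid2": r2[keep] * s2,
                "liability1": lia1[keep],
                "liability2": lia2[keep],
            }
        )
        kept.append((father[keep], mother[keep], child[keep], comp))
        n_kept += int(keep.sum())

    father = np.concatenate([k[0] for k in kept])[:n_trios]
    mother = np.concatenate([k[1] for k in kept])[:n_trios]
    child = np.concatenate([k[2] for k in kept])[:n_trios]
    comp = pd.concat([k[3] for k in kept], ignore_index=True).iloc[:n_trios].reset_index(drop=True)

    comorbid = (
        np.asarray(comorbid_rule(comp), dtype=bool)
        if comorbid_rule is not None
        else np.zeros(n_trios, dtype=bool)
    )
    if comorbid.shape != (n_trios,):
        raise ValueError("comorbid_rule must return one boolean per trio")

    return TrioCohort(
        fam_ids=np.array([f"FAM{i + 1:04d}" for i in range(n_trios)], dtype=object),
        father=father,
        mother=mother,
        child=child,
        comorbid=comorbid,
        liability=comp["liability1"].to_numpy(),
        components=comp,
        snp_ids=np.asarray(panel.snp_ids),
    )
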