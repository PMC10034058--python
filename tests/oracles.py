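"""Independent brute-force reference implementations used only by tests.

These are written as directly as possible (explicit loops, set comprehensions,
closed forms) and deliberately share no code with the package.
"""

from __future__ import annotations

import numpy as np


def bf_select_shared(evidence_rows, min_studies, conditions=("ASD", "epilepsy")):
    """Nested set-comprehension filter over (mirna, condition, study) tuples."""
    mirnas = {r[0] for r in evidence_rows}
    return sorted(
        m
        for m in mirnas
        if all(
            len({r[2] for r in evidence_rows if r[0] == m and r[1] == c})
            >= min_studies
            for c in conditions
        )
    )


def bf_aggregate_targets(pred_rows, mirnas, universe, min_sources, thresholds):
    """pred_rows: (mirna, gene, source, score) tuples."""
    out = set()
    for g in universe:
        for m in mirnas:
            srcs = {
                r[2]
                for r in pred_rows
                if r[0] == m
                and r[1] == g
                and r[3] is not None
                and not (isinstance(r[3], float) and np.isnan(r[3]))
                and r[3] >= thresholds[r[2]]
            }
            if len(srcs) >= min_sources:
                out.add(g)
                break
    return out


def bf_top_quantile(genes_in_set, scores, q):
    """Sort-based top-q filter over the scored universe, ties retained."""
    scored = sorted(scores.items(), key=lambda kv: -kv[1])
    k = int(np.ceil(q * len(scored)))
    cutoff = scored[k - 1][1]
    keep = {g for g, s in scored if s >= cutoff}
    return set(genes_in_set) & keep


def bf_snp_annotation(bed_rows, chrom, bp):
    """O(m*k) containment scan; bed_rows: (chrom, start, end) 0-based half-open,
    positions 1-based.  Returns boolean per SNP."""
    out = []
    for c, p in zip(chrom, bp):
        hit = False
        for bc, a, b in bed_rows:
            if str(bc) == str(c) and a < p <= b:
                hit = True
                break
        out.append(hit)
    return np.array(out)


def bf_chi2_2x2(a, b, c, d):
    """Closed form N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def bf_fdr(pvals):
    """Benjamini-Hochberg step-up with explicit loops."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def bf_ld_scores(genotypes, bp, chrom, membership, window_kb):
    """All-pairs double loop with np.corrcoef and bias correction."""
    n, m = genotypes.shape
    P = membership.shape[1]
    ell = np.zeros((m, P))
    for j in range(m):
        for k in range(m):
            if str(chrom[j]) != str(chrom[k]):
                continue
            if abs(float(bp[j]) - float(bp[k])) > window_kb * 1000.0:
                continue
            if j == k:
                r2 = 1.0
            else:
                sj = genotypes[:, j].std()
                sk = genotypes[:, k].std()
                if sj == 0 or sk == 0:
                    r2 = 0.0
                else:
                    r2 = np.corrcoef(genotypes[:, j], genotypes[:, k])[0, 1] ** 2
            adj = r2 - (1.0 - r2) / (n - 2)
            for c in range(P):
                if membership[k, c]:
                    ell[j, c] += adj
    return ell


def bf_clump(snp, chrom, bp, p, genotypes, clump_r2, clump_kb):
    """Greedy clumping with explicit candidate scan and pairwise corrcoef."""
    m = len(snp)
    claimed = [False] * m
    order = sorted(range(m), key=lambda j: (p[j], str(chrom[j]), bp[j], snp[j]))
    index = []
    for j in order:
        if claimed[j]:
            continue
        index.append(snp[j])
        claimed[j] = True
        for k in range(m):
            if claimed[k] or str(chrom[k]) != str(chrom[j]):
                continue
            if abs(float(bp[k]) - float(bp[j])) > clump_kb * 1000.0:
                continue
            sj = genotypes[:, j].std()
            sk = genotypes[:, k].std()
            r2 = (
                0.0
                if sj == 0 or sk == 0
                else np.corrcoef(genotypes[:, j], genotypes[:, k])[0, 1] ** 2
            )
            if r2 >= clump_r2:
                claimed[k] = True
    return index


def bf_score(dosages, betas):
    """Explicit per-individual dot product."""
    n = dosages.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(dosages.shape[1]):
            s += dosages[i, j] * betas[j]
        out[i] = s
    return out


def bf_welch(mean_a, se_a, mean_b, se_b):
    return (mean_a - mean_b) / np.sqrt(se_a**2 + se_b**2)
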