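"""Demo inputs: the curated miRNA dysregulation evidence and synthetic tables.

The published cross-disorder miRNA literature reduces to a structured evidence
table (miRNA, condition, study, direction); `mirna_dysregulation_evidence`
encodes the 14 replicated miRNAs with their reported dysregulation directions,
plus non-replicated decoys that the selection filter must reject.  Prediction
scores, gene coordinates, expression lists, and haploinsufficiency scores are
synthetic stand-ins generated at call time — they emulate the shape of the
external databases, not their content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PREDICTION_SOURCES = ("DIANA", "TargetScan", "PicTar", "Miranda", "miRDB")

# replicated dual-condition miRNAs with reported dysregulation directions
_SHARED_MIRNAS = {
    "let-7": ("Down", "Down/Up"),
    "miR-21": ("Up", "Down/Up"),
    "miR-27": ("Down", "Up"),
    "miR-34": ("Up", "Down/Up"),
    "miR-92": ("Up", "Down"),
    "miR-124": ("Up", "Down/Up"),
    "miR-129": ("Up", "Up"),
    "miR-145": ("Down/Up", "Down/Up"),
    "miR-146": ("Up", "Up"),
    "miR-155": ("Up", "Up"),
    "miR-181": ("Down/Up", "Up"),
    "miR-193": ("Down", "Up"),
    "miR-199": ("Up", "Up"),
    "miR-223": ("Up", "Down/Up"),
}

# decoys: dysregulation reported, but not replicated in both conditions
_DECOYS = [
    ("miR-9", "ASD", ["S1", "S2"], "Up"),
    ("miR-132", "epilepsy", ["S1", "S2"], "Down"),
    ("miR-128", "ASD", ["S1"], "Up"),
    ("miR-128", "epilepsy", ["S2"], "Up"),
]


def mirna_dysregulation_evidence() -> pd.DataFrame:
    """Structured evidence table with >=2 studies per condition for the 14
    shared miRNAs ("Down/Up" directions expand to one study of each sign) and
    under-replicated decoy miRNAs."""
    rows = []
    for mir, (d_asd, d_epi) in _SHARED_MIRNAS.items():
        for cond, d in (("ASD", d_asd), ("epilepsy", d_epi)):
            dirs = d.split("/") if "/" in d else [d, d]
            for i, direction in enumerate(dirs, start=1):
                rows.append((mir, cond, f"{mir}_{cond}_study{i}", direction.lower()))
    for mir, cond, studies, d in _DECOYS:
        for s in studies:
            rows.append((mir, cond, f"{mir}_{cond}_{s}", d.lower()))
    return pd.DataFrame(rows, columns=["mirna", "condition", "study_id", "direction"])


def shared_mirna_names() -> list:
    return sorted(_SHARED_MIRNAS)


def synthetic_gene_universe(
    n_genes: int,
    panel=None,
    gene_bp: int | None = None,
    gene_coverage: float = 0.55,
) -> tuple:
    """Gene ids plus non-overlapping coordinates spread over the panel's span.

    Returns (universe list, coords dict gene -> (chrom, start, end)) with
    0-based half-open intervals separated by intergenic gaps: gene bodies
    cover ``gene_coverage`` of the span, so a realistic fraction of panel SNPs
    falls outside every gene (intergenic SNPs identify the regression
    intercept in the covariance model, as they do in real annotations).
    """
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    if panel is None:
        span, chrom = n_genes * 100_000, "1"
    else:
        span, chrom = int(panel.bp.max()), str(panel.chrom[0])
    pitch = max(1, span // n_genes)
    if gene_bp is None:
        gene_bp = max(1, int(gene_coverage * pitch))
    gene_bp = min(gene_bp, pitch)
    coords = {}
    for i, g in enumerate(genes):
        start = i * pitch
        coords[g] = (chrom, start, start + gene_bp)
    return genes, coords


def synthetic_target_predictions(
    mirnas,
    universe,
    target_fraction: float = 0.10,
    consensus_prob: float = 0.50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random multi-source prediction scores with planted consensus structure.

    Each miRNA gets a random candidate-target subset; candidate genes score
    high (above the later per-source median) in each source with probability
    ``consensus_prob``, so a fraction of candidates reach 4-of-5 consensus.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    rows = []
    for mir in mirnas:
        k = max(1, int(target_fraction * len(universe)))
        cands = rng.choice(universe, size=k, replace=False)
        for g in cands:
            for src in PREDICTION_SOURCES:
                if rng.random() < consensus_prob:
                    s = rng.uniform(0.55, 1.0)  # above-median score
                else:
                    s = rng.uniform(0.0, 0.45)
                rows.append((mir, g, src, s))
    # background noise rows keep per-source medians near 0.5
    for src in PREDICTION_SOURCES:
        for g in rng.choice(universe, size=len(universe) // 2, replace=False):
            rows.append(("miR-background", g, src, rng.uniform(0.0, 1.0)))
    return pd.DataFrame(rows, columns=["mirna", "gene", "source", "score"])


def synthetic_gene_scores(universe, seed: int | None = None) -> dict:
    """Uniform(0,1) gene-level scores (haploinsufficiency stand-in)."""
    rng = np.random.default_rng(seed)
    return {g: float(rng.random()) for g in universe}


def synthetic_expression_list(universe, fraction: float = 0.77, seed=None) -> set:
    """Random brain-expressed membership list covering ``fraction`` of genes."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    k = int(fraction * len(universe))
    return set(rng.choice(universe, size=k, replace=False))
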