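"""Shared configuration for the demo analysis: one synthetic two-disorder
study emulating the real pipeline's shape (evidence table -> consensus target
partitions -> two GWAS -> ascertained trio cohort).

Scripts 01-04 rebuild these objects deterministically from the seeds below
instead of passing large genotype files between steps; `02_simulate_cohorts`
additionally writes the interchange files for inspection.
"""

from pathlib import Path

import numpy as np
from scipy.stats import norm

from mirepi import datasets, genesets as gs
from mirepi.simulate import draw_effects, make_reference_panel, simulate_trios

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED_PANEL = 71
SEED_PRED = 72
SEED_EFFECTS = 73
SEED_GWAS = 74
SEED_TRIOS = 75
SEED_NULL = 76
SEED_PERM = 77

N_GENES = 300
N_GWAS = 20_000          # per-trait discovery sample size
H2_ASD, H2_EPI = 0.20, 0.15
RHO_MIR, RHO_NOMIR = -0.03, 0.0   # planted genetic covariance per partition
N_TRIOS = 233            # trio cohort size (36 comorbid expected)
COMORBID_RATE = 36 / 233


def make_panel():
    """Reference panel: 500 individuals, 800 blocks x 3 SNPs, AR(1) r=0.4."""
    return make_reference_panel(500, 800, 3, 0.4, seed=SEED_PANEL)


def build_genesets(panel):
    """Evidence -> shared miRNAs -> consensus targets -> miR/no_miR partition."""
    evidence = datasets.mirna_dysregulation_evidence()
    shared = gs.select_shared_mirnas(evidence, min_studies_per_condition=2)
    genes, coords = datasets.synthetic_gene_universe(N_GENES, panel)
    pred = datasets.synthetic_target_predictions(shared, genes, seed=SEED_PRED)
    targets, counts = gs.aggregate_targets(pred, shared, genes, min_sources=4)
    no_mir = targets.complement("no_miR")
    bed_mir, _ = gs.genes_to_bed(sorted(targets.genes), coords)
    bed_nomir, _ = gs.genes_to_bed(sorted(no_mir.genes), coords)
    ann = gs.snp_annotation({"miR": bed_mir, "no_miR": bed_nomir}, panel)
    return {
        "evidence": evidence,
        "shared": shared,
        "genes": genes,
        "coords": coords,
        "predictions": pred,
        "targets": targets,
        "counts": counts,
        "no_mir": no_mir,
        "annotation": ann,
        "beds": {"miR": bed_mir, "no_miR": bed_nomir},
    }


def make_effects(annotation):
    return draw_effects(
        annotation, H2_ASD, H2_EPI, {"miR": RHO_MIR, "no_miR": RHO_NOMIR},
        seed=SEED_EFFECTS,
    )


def comorbid_rule(components):
    """Comorbid label: trait-2 liability above its expected upper quantile."""
    thr = norm.ppf(1 - COMORBID_RATE)
    return (components["liability2"] > thr).to_numpy()


def make_trios(panel, effects):
    return simulate_trios(
        panel, effects, N_TRIOS, "liability_top_q", top_q=0.1,
        seed=SEED_TRIOS, comorbid_rule=comorbid_rule,
    )
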