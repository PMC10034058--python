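import numpy as np
import pytest

from mirepi import datasets, genesets as gs
from mirepi.simulate import draw_effects, make_reference_panel

GLOBAL_SEED = 0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(GLOBAL_SEED)


@pytest.fixture(scope="session")
def small_panel():
    """400 individuals, 10 LD blocks x 20 SNPs, moderate within-block LD."""
    return make_reference_panel(
        400, n_blocks=10, snps_per_block=20, within_block_r=0.6, seed=11
    )


@pytest.fixture(scope="session")
def small_annotation(small_panel):
    genes, coords = datasets.synthetic_gene_universe(40, small_panel)
    bed_a, _ = gs.genes_to_bed(genes[:20], coords)
    bed_b, _ = gs.genes_to_bed(genes[20:], coords)
    return gs.snp_annotation({"miR": bed_a, "no_miR": bed_b}, small_panel)


@pytest.fixture(scope="session")
def small_effects(small_annotation):
    return draw_effects(
        small_annotation, 0.4, 0.3, {"miR": 0.02, "no_miR": -0.02}, seed=12
    )
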