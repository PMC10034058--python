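"""Construction of miRNA-target gene-set partitions.

This module turns a structured dysregulation-evidence table and multi-source
target-prediction tables into genomic partitions: the set of genes targeted by
miRNAs dysregulated in both disorders ("miR"), its complement among protein
coding genes ("no_miR"), optional expression / haploinsufficiency refinements,
gene-body BED intervals, and per-SNP partition membership against a reference
panel.  A 2x2 chi-square test quantifies over/under-representation of one gene
set within another.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "GeneSet",
    "SnpAnnotation",
    "select_shared_mirnas",
    "aggregate_targets",
    "filter_by_list",
    "top_quantile_filter",
    "genes_to_bed",
    "snp_annotation",
    "enrichment_2x2",
]

EVIDENCE_COLUMNS = ("mirna", "condition", "study_id", "direction")
PREDICTION_COLUMNS = ("mirna", "gene", "source", "score")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers within a fixed gene universe."""

    name: str
    genes: frozenset
    universe: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "universe", frozenset(self.universe))
        extra = self.genes - self.universe
        if extra:
            raise ValueError(f"genes outside universe: {sorted(extra)[:5]} ...")

    def __len__(self):
        return len(self.genes)

    def complement(self, name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"non_{self.name}", self.universe - self.genes, self.universe)


@dataclass
class SnpAnnotation:
    """Binary membership of each panel SNP in each named partition.

    ``membership`` is a boolean DataFrame indexed by SNP id with one column per
    partition, in panel SNP order.
    """

    snp_ids: np.ndarray
    membership: pd.DataFrame

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.membership = self.membership.astype(bool)
        if not np.array_equal(self.membership.index.to_numpy(), self.snp_ids):
            self.membership = self.membership.loc[self.snp_ids]

    @property
    def partitions(self) -> list:
        return list(self.membership.columns)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def counts(self) -> dict:
        return {c: int(self.membership[c].sum()) for c in self.partitions}

    def is_disjoint(self, names: Sequence[str] | None = None) -> bool:
        cols = list(names) if names is not None else self.partitions
        return bool((self.membership[cols].sum(axis=1) <= 1).all())

    def mask(self, name: str) -> np.ndarray:
        return self.membership[name].to_numpy()

    def partition_of_snp(self, fill: str = "intergenic") -> np.ndarray:
        """Single label per SNP; requires disjoint partitions."""
        if not self.is_disjoint():
            raise ValueError("partitions overlap; no unique label per SNP")
        out = np.full(self.n_snps, fill, dtype=object)
        for c in self.partitions:
            out[self.mask(c)] = c
        return out

    def with_complement(self, name: str = "intergenic") -> "SnpAnnotation":
        mem = self.membership.copy()
        mem[name] = ~mem.any(axis=1)
        return SnpAnnotation(self.snp_ids, mem)


def _as_frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=list(columns))
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return df


def select_shared_mirnas(
    evidence,
    min_studies_per_condition: int = 2,
    conditions: Sequence[str] = ("ASD", "epilepsy"),
) -> list:
    """miRNAs with >= `min_studies_per_condition` distinct studies in each condition.

    The evidence table has one row per (mirna, condition, study_id) finding of
    significant case/control dysregulation.  Requiring at least two independent
    studies per condition keeps only replicated findings.
    """
    if min_studies_per_condition < 1:
        raise ValueError("min_studies_per_condition must be >= 1")
    ev = _as_frame(evidence, EVIDENCE_COLUMNS)
    if len(ev) == 0:
        return []
    unknown = set(ev["condition"]) - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    counts = (
        ev.drop_duplicates(["mirna", "condition", "study_id"])
        .groupby(["mirna", "condition"])["study_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=list(conditions), fill_value=0)
    )
    ok = (counts >= min_studies_per_condition).all(axis=1)
    return sorted(counts.index[ok])


def aggregate_targets(
    predictions,
    mirnas: Iterable,
    universe: Iterable,
    min_sources: int = 4,
    per_source_threshold: Mapping[str, float] | None = None,
) -> tuple[GeneSet, pd.Series]:
    """Consensus target set: genes predicted by >= `min_sources` sources.

    A gene is a consensus target of a miRNA when its prediction score is
    non-missing and at or above the per-source cutoff in at least
    ``min_sources`` distinct sources.  The returned set is the union over the
    selected miRNAs, restricted to the gene universe; per-miRNA target counts
    are returned alongside.  When ``per_source_threshold`` is not supplied the
    cutoff for each source defaults to the median of that source's supplied
    scores.
    """
    pred = _as_frame(predictions, PREDICTION_COLUMNS)
    universe = frozenset(universe)
    mirnas = set(mirnas)
    sources = sorted(pred["source"].unique())
    n_sources = len(sources)
    if n_sources and not 1 <= min_sources <= n_sources:
        raise ValueError(f"min_sources={min_sources} outside 1..{n_sources}")
    if per_source_threshold is None:
        per_source_threshold = {
            s: float(pred.loc[pred["source"] == s, "score"].median()) for s in sources
        }
    else:
        unknown = set(sources) - set(per_source_threshold)
        if unknown:
            raise ValueError(f"no threshold for sources: {sorted(unknown)}")

    sub = pred[pred["mirna"].isin(mirnas) & pred["gene"].isin(universe)].copy()
    sub = sub.dropna(subset=["score"])
    cut = sub["source"].map(per_source_threshold)
    sub = sub[sub["score"] >= cut]
    if len(sub) == 0:
        counts = pd.Series(0, index=sorted(mirnas), dtype=int)
        return GeneSet("targets", frozenset(), universe), counts
    nsrc = sub.groupby(["mirna", "gene"])["source"].nunique()
    hits = nsrc[nsrc >= min_sources].reset_index()
    genes = frozenset(hits["gene"])
    counts = (
        hits.groupby("mirna")["gene"].nunique().reindex(sorted(mirnas), fill_value=0)
    )
    return GeneSet("targets", genes, universe), counts


def filter_by_list(gs: GeneSet, keep: Iterable, name: str) -> GeneSet:
    """Intersect a gene set with a membership list (universe unchanged)."""
    return GeneSet(name, gs.genes & frozenset(keep), gs.universe)


def top_quantile_filter(
    gs: GeneSet, scores: Mapping[str, float], q: float, name: str | None = None
) -> tuple[GeneSet, float]:
    """Keep members whose score lies in the top-q fraction of the universe.

    The cutoff is the score of the ceil(q * n_scored)-th highest-scoring gene
    over the whole universe (not within ``gs``); ties at the cutoff are all
    retained.  Genes without a score are excluded.  Returns the filtered set
    and the cutoff used.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if not gs.universe:
        raise ValueError("empty universe")
    if q == 1:
        return GeneSet(name or f"{gs.name}_top100pct", gs.genes, gs.universe), -np.inf
    sc = pd.Series(scores)
    sc = sc[sc.index.isin(gs.universe)].dropna()
    if len(sc) == 0:
        raise ValueError("no scored genes in universe")
    k = int(np.ceil(q * len(sc)))
    cutoff = float(np.sort(sc.to_numpy())[::-1][k - 1])
    keep = frozenset(sc.index[sc >= cutoff])
    out = GeneSet(name or f"{gs.name}_top{q:g}", gs.genes & keep, gs.universe)
    return out, cutoff


def genes_to_bed(
    genes: Iterable, coords: Mapping[str, tuple]
) -> tuple[pd.DataFrame, list]:
    """Gene-body intervals as a BED-style frame (0-based half-open).

    One interval per gene, sorted by (chrom, start, gene); overlapping
    intervals are deliberately not merged — membership, not coverage, is the
    downstream semantics.  Genes without coordinates are skipped with a
    warning; their ids are returned.
    """
    rows, skipped = [], []
    for g in genes:
        if g not in coords:
            skipped.append(g)
            continue
        chrom, start, end = coords[g]
        if not start < end:
            raise ValueError(f"{g}: start must be < end ({start}, {end})")
        rows.append((str(chrom), int(start), int(end), g))
    if skipped:
        warnings.warn(f"{len(skipped)} gene(s) without coordinates skipped")
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    bed = bed.sort_values(["chrom", "start", "gene"], kind="stable").reset_index(drop=True)
    return bed, skipped


def snp_annotation(bed_by_partition: Mapping[str, pd.DataFrame], panel) -> SnpAnnotation:
    """Per-SNP partition membership from BED intervals.

    Panel positions are 1-based; BED intervals [a, b) are 0-based half-open, so
    a SNP at 1-based position p falls in [a, b) iff a < p <= b.
    """
    panel_chroms = set(np.asarray(panel.chrom, dtype=str))
    mem = {}
    for name, bed in bed_by_partition.items():
        bad = sorted(set(bed["chrom"].astype(str)) - panel_chroms)
        if bad:
            raise ValueError(f"partition {name!r}: chromosomes absent from panel: {bad}")
        trees = {}
        for chrom, grp in bed.groupby("chrom"):
            t = IntervalTree()
            for a, b in zip(grp["start"], grp["end"]):
                t[int(a):int(b)] = True
            trees[str(chrom)] = t
        hits = np.zeros(panel.n_snps, dtype=bool)
        for j, (c, p) in enumerate(zip(np.asarray(panel.chrom, dtype=str), panel.bp)):
            t = trees.get(c)
            if t is not None and t.overlaps_point(int(p) - 1):
                hits[j] = True
        mem[name] = hits
    df = pd.DataFrame(mem, index=pd.Index(panel.snp_ids, name="SNP"))
    return SnpAnnotation(np.asarray(panel.snp_ids), df)


Enrichment2x2 = namedtuple("Enrichment2x2", ["chi2", "p", "table", "low_expected"])


def enrichment_2x2(set_a: GeneSet, set_b: GeneSet) -> Enrichment2x2:
    """Pearson chi-square (no continuity correction) on in/out-of-A x in/out-of-B."""
    if set_a.universe != set_b.universe:
        raise ValueError("gene sets must share a universe")
    a = len(set_a.genes & set_b.genes)
    b = len(set_a.genes - set_b.genes)
    c = len(set_b.genes - set_a.genes)
    d = len(set_a.universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    low = bool((res.expected_freq < 1).any())
    if low:
        warnings.warn("2x2 expected cell < 1; chi-square approximation unreliable")
    return Enrichment2x2(float(res.statistic), float(res.pvalue), table, low)
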