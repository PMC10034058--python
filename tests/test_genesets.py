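"""Gene-set construction: shared-miRNA selection, consensus targets, filters,
BED/annotation coordinate conventions, and the 2x2 chi-square."""

import numpy as np
import pandas as pd
import pytest

from mirepi import datasets
from mirepi.genesets import (
    GeneSet,
    aggregate_targets,
    enrichment_2x2,
    filter_by_list,
    genes_to_bed,
    select_shared_mirnas,
    snp_annotation,
    top_quantile_filter,
)
from oracles import (
    bf_aggregate_targets,
    bf_chi2_2x2,
    bf_select_shared,
    bf_snp_annotation,
    bf_top_quantile,
)


class TestSelectSharedMirnas:
    def test_empty_evidence(self):
        assert select_shared_mirnas(pd.DataFrame(columns=["mirna", "condition", "study_id", "direction"])) == []

    def test_replicated_dual_condition_mirnas_selected(self):
        """The curated evidence table yields exactly the 14 dual-condition
        miRNAs (miR-146 among them); decoys with <2 studies in a condition
        are rejected."""
        ev = datasets.mirna_dysregulation_evidence()
        picked = select_shared_mirnas(ev, min_studies_per_condition=2)
        assert picked == datasets.shared_mirna_names()
        assert "miR-146" in picked
        assert "miR-9" not in picked and "miR-128" not in picked

    def test_unknown_condition_rejected(self):
        ev = pd.DataFrame(
            [["miR-1", "diabetes", "s1", "up"]],
            columns=["mirna", "condition", "study_id", "direction"],
        )
        with pytest.raises(ValueError, match="unknown condition"):
            select_shared_mirnas(ev)

    def test_matches_bruteforce_on_random_tables(self, rng):
        for _ in range(100):
            n = rng.integers(1, 40)
            rows = [
                (
                    f"miR-{rng.integers(1, 8)}",
                    ("ASD", "epilepsy")[rng.integers(2)],
                    f"s{rng.integers(1, 5)}",
                    ("up", "down")[rng.integers(2)],
                )
                for _ in range(n)
            ]
            df = pd.DataFrame(rows, columns=["mirna", "condition", "study_id", "direction"])
            k = int(rng.integers(1, 4))
            assert select_shared_mirnas(df, k) == bf_select_shared(rows, k)


class TestAggregateTargets:
    UNIVERSE = [f"G{i}" for i in range(20)]
    SOURCES = list(datasets.PREDICTION_SOURCES)

    def _random_predictions(self, rng, n):
        rows = [
            (
                f"miR-{rng.integers(1, 4)}",
                f"G{rng.integers(0, 20)}",
                self.SOURCES[rng.integers(5)],
                float(rng.random()),
            )
            for _ in range(n)
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "source", "score"]).drop_duplicates(
            ["mirna", "gene", "source"]
        )

    def test_five_of_five_included_three_of_five_excluded(self):
        rows = [("miR-21", "G0", s, 0.9) for s in self.SOURCES]
        rows += [("miR-21", "G1", s, 0.9) for s in self.SOURCES[:3]]
        pred = pd.DataFrame(rows, columns=["mirna", "gene", "source", "score"])
        thr = {s: 0.5 for s in self.SOURCES}
        gs4, counts = aggregate_targets(pred, ["miR-21"], self.UNIVERSE, 4, thr)
        assert gs4.genes == {"G0"}
        assert counts["miR-21"] == 1

    def test_monotone_in_min_sources(self, rng):
        pred = self._random_predictions(rng, 300)
        thr = {s: 0.5 for s in self.SOURCES}
        mirnas = ["miR-1", "miR-2", "miR-3"]
        sizes = [
            len(aggregate_targets(pred, mirnas, self.UNIVERSE, k, thr)[0].genes)
            for k in range(1, 6)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_bruteforce_on_random_tables(self, rng):
        thr = {s: 0.5 for s in self.SOURCES}
        for _ in range(100):
            pred = self._random_predictions(rng, int(rng.integers(10, 200)))
            k = int(rng.integers(1, pred["source"].nunique() + 1))
            mirnas = ["miR-1", "miR-2"]
            got, _ = aggregate_targets(pred, mirnas, self.UNIVERSE, k, thr)
            want = bf_aggregate_targets(
                list(pred.itertuples(index=False)), mirnas, self.UNIVERSE, k, thr
            )
            assert got.genes == want

    def test_unknown_source_threshold_missing(self):
        pred = pd.DataFrame(
            [("miR-1", "G0", "DIANA", 0.9)], columns=["mirna", "gene", "source", "score"]
        )
        with pytest.raises(ValueError, match="no threshold"):
            aggregate_targets(pred, ["miR-1"], self.UNIVERSE, 1, {"TargetScan": 0.5})


class TestFilters:
    def _gs(self, genes, universe=None):
        universe = universe if universe is not None else genes
        return GeneSet("g", frozenset(genes), frozenset(universe))

    def test_filter_by_list_identity_and_empty(self):
        gs = self._gs({"a", "b"}, {"a", "b", "c"})
        assert filter_by_list(gs, gs.universe, "x").genes == gs.genes
        assert filter_by_list(gs, set(), "x").genes == set()

    def test_filter_by_list_random_sets(self, rng):
        universe = [f"G{i}" for i in range(50)]
        for _ in range(50):
            genes = set(rng.choice(universe, size=rng.integers(0, 50), replace=False))
            keep = set(rng.choice(universe, size=rng.integers(0, 50), replace=False))
            out = filter_by_list(self._gs(genes, universe), keep, "x")
            assert out.genes == genes & keep
            assert out.universe == frozenset(universe)

    def test_top_quantile_simple_and_degenerate(self):
        universe = ["a", "b", "c", "d"]
        scores = {"a": 1, "b": 2, "c": 3, "d": 4}
        gs = self._gs(set(universe), universe)
        out, cutoff = top_quantile_filter(gs, scores, 0.25)
        assert out.genes == {"d"} and cutoff == 4
        out1, _ = top_quantile_filter(gs, scores, 1.0)
        assert out1.genes == gs.genes

    def test_top_quantile_ties_retained(self, rng):
        universe = [f"G{i}" for i in range(30)]
        for _ in range(50):
            scores = {g: float(rng.integers(0, 5)) for g in universe}
            gs = self._gs(set(universe), universe)
            q = float(rng.choice([0.1, 0.25, 0.5, 0.9]))
            out, _ = top_quantile_filter(gs, scores, q)
            assert out.genes == bf_top_quantile(universe, scores, q)

    def test_missing_scores_excluded(self):
        universe = ["a", "b", "c", "d"]
        scores = {"a": 1.0, "b": 2.0, "c": 3.0}  # d unscored
        out, _ = top_quantile_filter(self._gs(set(universe), universe), scores, 0.5)
        assert "d" not in out.genes

    def test_filter_composition_equals_intersection(self, rng):
        universe = [f"G{i}" for i in range(40)]
        scores = {g: float(rng.random()) for g in universe}
        keep = set(rng.choice(universe, size=20, replace=False))
        gs = self._gs(set(rng.choice(universe, size=25, replace=False)), universe)
        comp, _ = top_quantile_filter(filter_by_list(gs, keep, "e"), scores, 0.25)
        alone, _ = top_quantile_filter(gs, scores, 0.25)
        assert comp.genes == alone.genes & filter_by_list(gs, keep, "e").genes


class TestBedAndAnnotation:
    def test_single_gene_interval(self):
        bed, skipped = genes_to_bed(["g1"], {"g1": ("chr1", 100, 200)})
        assert skipped == []
        assert bed.iloc[0].tolist() == ["chr1", 100, 200, "g1"]

    def test_same_locus_stable_order_and_missing_warned(self):
        coords = {"b": ("1", 10, 20), "a": ("1", 10, 20)}
        with pytest.warns(UserWarning, match="without coordinates"):
            bed, skipped = genes_to_bed(["b", "a", "zz"], coords)
        assert bed["gene"].tolist() == ["a", "b"]
        assert skipped == ["zz"]

    def test_bed_round_trip(self, tmp_path, rng):
        from mirepi.io import read_bed, write_bed

        coords = {
            f"g{i}": ("1", int(a), int(a) + int(rng.integers(1, 500)))
            for i, a in enumerate(rng.integers(0, 10_000, size=30))
        }
        bed, _ = genes_to_bed(list(coords), coords)
        write_bed(bed, tmp_path / "x.bed")
        back = read_bed(tmp_path / "x.bed")
        pd.testing.assert_frame_equal(bed, back)

    def test_boundary_convention(self, small_panel):
        """BED [a, b) contains 1-based position p iff a < p <= b."""
        bp0 = int(small_panel.bp[0])
        bed_out = pd.DataFrame(
            [["1", bp0, bp0 + 1, "gA"]], columns=["chrom", "start", "end", "gene"]
        )
        ann = snp_annotation({"hit": bed_out}, small_panel)
        assert not ann.mask("hit")[0]  # interval starting AT bp excludes it
        bed_in = pd.DataFrame(
            [["1", bp0 - 1, bp0, "gA"]], columns=["chrom", "start", "end", "gene"]
        )
        ann = snp_annotation({"hit": bed_in}, small_panel)
        assert ann.mask("hit")[0]

    def test_chromosome_mismatch_reported(self, small_panel):
        bed = pd.DataFrame([["chrX", 0, 10, "g"]], columns=["chrom", "start", "end", "gene"])
        with pytest.raises(ValueError, match="chrX"):
            snp_annotation({"p": bed}, small_panel)

    def test_matches_bruteforce_containment(self, small_panel, rng):
        span = int(small_panel.bp.max())
        for _ in range(100):
            k = int(rng.integers(1, 12))
            starts = rng.integers(0, span, size=k)
            rows = [
                ("1", int(a), int(a) + int(rng.integers(1, 40_000))) for a in starts
            ]
            bed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            bed["gene"] = [f"g{i}" for i in range(k)]
            ann = snp_annotation({"p": bed}, small_panel)
            want = bf_snp_annotation(rows, small_panel.chrom, small_panel.bp)
            assert np.array_equal(ann.mask("p"), want)

    def test_partition_completeness(self, small_annotation):
        full = small_annotation.with_complement("intergenic")
        assert full.membership.sum(axis=1).eq(1).all()
        assert small_annotation.is_disjoint()


class TestEnrichment2x2:
    def test_independence_gives_zero(self):
        universe = [f"G{i}" for i in range(40)]
        a = GeneSet("a", universe[:20], universe)
        b = GeneSet("b", universe[:10] + universe[20:30], universe)
        chi2, p, table, low = enrichment_2x2(a, b)
        assert table.tolist() == [[10, 10], [10, 10]]
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_closed_form_20_10_10_20(self):
        universe = [f"G{i}" for i in range(60)]
        a = GeneSet("a", universe[:30], universe)
        b = GeneSet("b", universe[:20] + universe[30:40], universe)
        chi2, p, table, low = enrichment_2x2(a, b)
        assert table.tolist() == [[20, 10], [10, 20]]
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(100):
            universe = [f"G{i}" for i in range(int(rng.integers(8, 200)))]
            ga = set(rng.choice(universe, size=rng.integers(2, len(universe)), replace=False))
            gb = set(rng.choice(universe, size=rng.integers(2, len(universe)), replace=False))
            if not (ga - gb) or not (gb - ga) or not (set(universe) - ga - gb):
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi2, _, t, _ = enrichment_2x2(
                    GeneSet("a", ga, universe), GeneSet("b", gb, universe)
                )
            a, b = t[0]
            c, d = t[1]
            assert chi2 == pytest.approx(bf_chi2_2x2(a, b, c, d), rel=1e-10)

    def test_mismatched_universe_rejected(self):
        a = GeneSet("a", {"x"}, {"x", "y"})
        b = GeneSet("b", {"x"}, {"x", "z"})
        with pytest.raises(ValueError, match="universe"):
            enrichment_2x2(a, b)
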