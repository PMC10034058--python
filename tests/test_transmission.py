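"""Clumping, polygenic scoring, pTDT, threshold selection, permutations, and
the two-group contrast."""

import numpy as np
import pandas as pd
import pytest

from mirepi.simulate import draw_effects, make_reference_panel, simulate_sumstats, simulate_trios
from mirepi.transmission import (
    DEFAULT_THRESHOLDS,
    PRSConfig,
    clump,
    compare_groups,
    permutation_test,
    ptdt,
    score,
    score_thresholds,
    se_from_ci,
    select_best_threshold,
    welch_from_summaries,
)
from oracles import bf_clump, bf_score, bf_welch


@pytest.fixture(scope="module")
def trio_setup(small_panel, small_annotation):
    eff = draw_effects(small_annotation, 0.4, 0.3, {"miR": 0.0, "no_miR": 0.0}, seed=90)
    trios = simulate_trios(small_panel, eff, 120, seed=91)
    ss, _ = simulate_sumstats(small_panel, eff, 2000, 2000, seed=92)
    return small_panel, small_annotation, trios, ss


class TestPRSConfig:
    def test_defaults_match_standard_settings(self):
        cfg = PRSConfig()
        assert cfg.clump_r2 == 0.1 and cfg.clump_kb == 500
        assert cfg.thresholds == (5e-5, 0.001, 0.01, 0.05, 0.1, 0.2)

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            PRSConfig(thresholds=(0.1, 0.05))


class TestClump:
    def test_mutually_uncorrelated_snps_all_indices(self):
        panel = make_reference_panel(200, 10, 1, 0.0, seed=101, bp_spacing=2_000_000)
        ss, _ = _null_ss(panel, seed=102)
        idx = clump(ss, panel, clump_r2=0.1, clump_kb=500)
        assert sorted(idx) == sorted(panel.snp_ids)

    def test_duplicated_snp_keeps_smaller_p(self):
        panel = make_reference_panel(200, 1, 2, 0.999, seed=103, bp_spacing=5_000)
        ss, _ = _null_ss(panel, seed=104)
        r2 = np.corrcoef(panel.genotypes[:, 0], panel.genotypes[:, 1])[0, 1] ** 2
        assert r2 > 0.5  # near-duplicate pair
        idx = clump(ss, panel, clump_r2=0.5, clump_kb=500)
        best = ss.loc[ss["P"].idxmin(), "SNP"]
        assert idx == [best]

    def test_empty_input(self, small_panel):
        assert clump(pd.DataFrame(columns=["SNP", "CHR", "BP", "P"]), small_panel) == []

    def test_matches_bruteforce_greedy(self, rng):
        for _ in range(30):
            panel = make_reference_panel(
                60, 6, 5, float(rng.uniform(0, 0.95)),
                seed=int(rng.integers(1e6)), bp_spacing=int(rng.integers(50, 1500) * 1000),
            )
            ss, _ = _null_ss(panel, seed=int(rng.integers(1e6)))
            r2 = float(rng.choice([0.052, 0.1003, 0.3007, 0.799]))
            kb = float(rng.choice([100, 500, 2000]))
            got = clump(ss, panel, r2, kb)
            want = bf_clump(
                list(map(str, panel.snp_ids)), panel.chrom, panel.bp,
                ss.set_index("SNP").loc[map(str, panel.snp_ids), "P"].to_numpy(),
                panel.genotypes.astype(float), r2, kb,
            )
            assert got == want


def _null_ss(panel, seed):
    import pandas as pd

    from mirepi import genesets as gs

    ann = gs.SnpAnnotation(
        panel.snp_ids,
        pd.DataFrame(
            {"all": np.ones(panel.n_snps, bool)}, index=pd.Index(panel.snp_ids)
        ),
    )
    eff = draw_effects(ann, 0.3, 0.0, {"all": 0.0}, seed=seed)
    return simulate_sumstats(panel, eff, 500, 500, seed=seed + 1)


class TestScore:
    def test_single_snp_score(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        one = ss.iloc[[0]].copy()
        one["BETA"] = 0.5
        one["P"] = 1e-10
        prs = score(trios, one, {one["SNP"].iloc[0]}, 0.05)
        j = 0
        assert np.allclose(prs.child[:, 0], 0.5 * trios.child[:, j])

    def test_threshold_below_min_p_flagged(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        tiny = float(ss["P"].min()) / 10
        prs = score(trios, ss, set(ss["SNP"]), tiny)
        assert tiny in prs.flagged
        with pytest.raises(ValueError, match="flagged"):
            ptdt(prs, trios)

    def test_matches_dot_product_oracle(self, trio_setup, rng):
        panel, ann, trios, ss = trio_setup
        for _ in range(20):
            chosen = rng.choice(ss["SNP"], size=20, replace=False)
            th = float(rng.choice([0.05, 0.2, 0.5, 1.0]))
            prs = score(trios, ss, set(chosen), th)
            sel = ss[ss["SNP"].isin(chosen) & (ss["P"] < th)]
            pos = {s: j for j, s in enumerate(trios.snp_ids)}
            cols = sel["SNP"].map(pos).to_numpy()
            if len(cols) == 0:
                assert th in prs.flagged
                continue
            want = bf_score(trios.child[:, cols].astype(float), sel["BETA"].to_numpy())
            assert np.allclose(prs.child[:, 0], want)

    def test_prs_linearity_across_thresholds(self, trio_setup):
        """Score at T equals score at T' < T plus the increment of SNPs with
        p in [T', T)."""
        panel, ann, trios, ss = trio_setup
        idx = set(ss["SNP"])
        prs = score_thresholds(trios, ss, idx, (0.05, 0.2))
        inc = ss[(ss["P"] >= 0.05) & (ss["P"] < 0.2)]
        pos = {s: j for j, s in enumerate(trios.snp_ids)}
        cols = inc["SNP"].map(pos).to_numpy()
        want = prs.child[:, 0] + trios.child[:, cols].astype(float) @ inc["BETA"].to_numpy()
        assert np.allclose(prs.child[:, 1], want)
        assert prs.n_snps[0.05] <= prs.n_snps[0.2]


class TestPtdt:
    def test_child_equals_midparent_convention(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        prs.child = (prs.father + prs.mother) / 2.0
        res = ptdt(prs, trios)
        assert res.mean_dev == 0.0 and res.p_t == 1.0

    def test_single_positive_deviation_gives_positive_mean(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        prs.child = (prs.father + prs.mother) / 2.0
        prs.child[0, 0] += 5.0
        assert ptdt(prs, trios).mean_dev > 0

    def test_location_scale_invariance(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        base = ptdt(prs, trios)
        prs.child = prs.child * 3.0 + 7.0
        prs.father = prs.father * 3.0 + 7.0
        prs.mother = prs.mother * 3.0 + 7.0
        moved = ptdt(prs, trios)
        assert np.allclose(moved.deviations, base.deviations)
        assert moved.p_t == pytest.approx(base.p_t)

    def test_zero_midparent_variance_rejected(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        prs.father[:] = 1.0
        prs.mother[:] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            ptdt(prs, trios)

    def test_group_mask_and_min_size(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        mask = np.zeros(trios.n_trios, bool)
        mask[:2] = True
        with pytest.raises(ValueError, match=">= 3 trios"):
            ptdt(prs, trios, group_mask=mask)


class TestSelectBestThreshold:
    def test_single_threshold_trivial(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 0.5)
        assert select_best_threshold(prs, trios) == 0.5

    def test_planted_extreme_threshold_selected(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score_thresholds(trios, ss, set(ss["SNP"]), (0.001, 0.01, 0.1))
        # plant an extreme transmission signal only in the 0.01 column
        k = prs.thresholds.index(0.01)
        prs.child[:, k] = (prs.father[:, k] + prs.mother[:, k]) / 2 + 10.0
        assert select_best_threshold(prs, trios) == 0.01

    def test_column_order_invariance(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score_thresholds(trios, ss, set(ss["SNP"]), (0.01, 0.1, 0.5))
        best = select_best_threshold(prs, trios)
        rev = score_thresholds(trios, ss, set(ss["SNP"]), (0.01, 0.1, 0.5))
        order = [2, 0, 1]
        rev.father = rev.father[:, order]
        rev.mother = rev.mother[:, order]
        rev.child = rev.child[:, order]
        rev.thresholds = tuple(np.array(rev.thresholds)[order])
        assert select_best_threshold(rev, trios) == best


class TestPermutationTest:
    def test_smoothing_bound_single_permutation(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        labels = np.zeros(trios.n_trios, bool)
        labels[:30] = True
        p1, p2 = permutation_test(prs, trios, labels, n_perm=1, seed=3)
        assert p1 in (0.5, 1.0) and p2 in (0.5, 1.0)

    def test_planted_group_difference_detected(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        labels = np.zeros(trios.n_trios, bool)
        labels[:30] = True
        prs.child[labels, 0] = (prs.father[labels, 0] + prs.mother[labels, 0]) / 2 - 10.0
        p1, _ = permutation_test(prs, trios, labels, n_perm=500, seed=4)
        assert p1 <= 0.05

    def test_reproducible_and_never_zero(self, trio_setup):
        panel, ann, trios, ss = trio_setup
        prs = score(trios, ss, set(ss["SNP"]), 1.0)
        labels = np.zeros(trios.n_trios, bool)
        labels[::4] = True
        a = permutation_test(prs, trios, labels, n_perm=200, seed=6)
        b = permutation_test(prs, trios, labels, n_perm=200, seed=6)
        assert a == b and min(a) > 0
        with pytest.raises(ValueError, match="seed"):
            permutation_test(prs, trios, labels, n_perm=10)


class TestCompareGroups:
    def _res(self, dev):
        from mirepi.transmission import PTDTResult

        dev = np.asarray(dev, float)
        return PTDTResult("g", len(dev), dev, float(dev.mean()), (0, 0), 0.0, 1.0)

    def test_identical_vectors_give_t_zero(self, rng):
        dev = rng.standard_normal(30)
        out = compare_groups(self._res(dev), self._res(dev.copy()))
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_closed_form_welch(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50) + 1.0
        out = compare_groups(self._res(a), self._res(b))
        t_want = bf_welch(a.mean(), a.std(ddof=1) / np.sqrt(50), b.mean(), b.std(ddof=1) / np.sqrt(50))
        assert out["t"] == pytest.approx(t_want, rel=1e-10)
        assert out["shapiro_a"] is not None and out["bartlett"] is not None

    def test_published_group_summaries_reconstruct_reported_t(self):
        """Group means/CIs/sizes as reported for the comorbid vs non-comorbid
        trio contrast give Welch t ~ 2.05."""
        se_epi = se_from_ci((0.8039 - 0.1060) / 2, 36)
        se_noepi = se_from_ci((0.2197 + 0.0802) / 2, 197)
        t, df = welch_from_summaries(-0.0697, se_noepi, 197, -0.4549, se_epi, 36)
        assert t == pytest.approx(2.0496, abs=0.01)

    def test_zero_variance_both_groups(self):
        out = compare_groups(self._res([1.0, 1.0, 1.0]), self._res([1.0, 1.0, 1.0]))
        assert out["t"] == 0.0 and out["p"] == 1.0
        with pytest.raises(ValueError, match="zero variance"):
            compare_groups(self._res([1.0, 1.0]), self._res([2.0, 2.0]))


class TestPtdtNullCalibration:
    def test_unascertained_trios_reject_at_nominal_rate(self, small_panel, small_annotation):
        """True-effect PRS in unascertained trios: the one-sample pTDT test
        should reject at ~5%; here we check the rate loosely over 60
        replicates (the full calibration lives in the acceptance suite)."""
        eff = draw_effects(small_annotation, 0.5, 0.0, {"miR": 0.0, "no_miR": 0.0}, seed=95)
        ss = pd.DataFrame(
            {
                "SNP": small_panel.snp_ids,
                "CHR": small_panel.chrom,
                "BP": small_panel.bp,
                "BETA": eff.beta1,
                "P": 1e-8,
            }
        )
        rej = 0
        n_rep = 60
        for rep in range(n_rep):
            trios = simulate_trios(small_panel, eff, 100, seed=9000 + rep)
            prs = score(trios, ss, set(ss["SNP"]), 1.0)
            if ptdt(prs, trios).p_t < 0.05:
                rej += 1
        assert 0 <= rej / n_rep < 0.15
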