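import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutmir.diffabund import (
    baseline_strain_tests,
    bh_fdr,
    blocked_rm_permutation_anova,
    classify_effect,
    genus_column,
    permutation_ttest,
    posthoc_paired_permutation_ttest,
    posthoc_treatment_tests,
    to_relative,
)
from gutmir.io import DataError, SampleMeta
from oracles import exhaustive_signflip_p, exhaustive_two_sample_p


class TestToRelative:
    def test_rows_sum_to_one(self, toy_table):
        rel = to_relative(toy_table)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_genus_collapse_pools_same_genus(self, toy_table):
        rel = to_relative(toy_table, collapse_to_genus=True)
        # two Blautia OTUs share one column; the f_;g_ OTU stays separate
        assert rel.shape[1] == 4
        blautia = genus_column(rel, "Blautia")
        otu_rel = to_relative(toy_table)
        np.testing.assert_allclose(
            rel[blautia], otu_rel["OTU2"] + otu_rel["OTU3"])
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_sum_sample_rejected(self, toy_table):
        import copy
        bad = copy.deepcopy(toy_table)
        bad.counts = bad.counts.copy()
        bad.counts[0] = 0
        with pytest.raises(DataError, match="S1"):
            to_relative(bad)


class TestPermutationTtest:
    def test_worked_example_exact(self):
        # C(6,3)=20 arrangements; only the observed and its mirror as extreme
        assert permutation_ttest([1, 2, 3], [10, 11, 12]) == \
            pytest.approx(2 / 20)

    def test_identical_multisets(self):
        assert permutation_ttest([1, 2, 2], [2, 1, 2]) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            assert permutation_ttest(x, y, n_perm=10_000) == \
                pytest.approx(exhaustive_two_sample_p(x, y))

    def test_null_p_uniform(self):
        rng = np.random.default_rng(23)
        ps = [permutation_ttest(rng.normal(size=5), rng.normal(size=5),
                                n_perm=10_000)
              for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(DataError):
            permutation_ttest([1.0], [2.0, 3.0])


class TestSignFlipTest:
    def test_all_zero_differences(self):
        assert posthoc_paired_permutation_ttest([1, 2, 3], [1, 2, 3]) == 1.0

    def test_worked_example(self):
        # six +1 differences: 2 of 64 sign patterns are as extreme
        p = posthoc_paired_permutation_ttest(np.zeros(6), np.ones(6))
        assert p == pytest.approx(2 / 64)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(31)
        pre = rng.normal(size=6)
        post = rng.normal(size=6)
        p1 = posthoc_paired_permutation_ttest(pre, post)
        p2 = posthoc_paired_permutation_ttest(post, pre)
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            d = rng.normal(size=7)
            p = posthoc_paired_permutation_ttest(np.zeros(7), d,
                                                 n_perm=10_000)
            assert p == pytest.approx(exhaustive_signflip_p(d))


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_all_ones(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(43)
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestClassifyEffect:
    def test_categories(self):
        assert classify_effect(0.01, 0.13, True, True) == ("up3", "B")
        assert classify_effect(0.05, 0.07, True, True) == ("up2", "B")
        assert classify_effect(0.010, 0.012, True, True) == ("up1", "B")
        assert classify_effect(0.2, 0.0, True, False) == ("only_A", "A")
        assert classify_effect(0.0, 0.001, False, True) == ("only_B", "B")

    def test_boundaries_resolve_weaker(self):
        # exactly 10% / 1% are NOT the stronger category
        assert classify_effect(0.0, 0.10, True, True)[0] == "up2"
        assert classify_effect(0.0, 0.01, True, True)[0] == "up1"

    def test_presence_shift(self):
        assert classify_effect(0.1, 0.1, True, True,
                               significant_presence_shift=True)[0] == \
            "presence"


class TestBaselineStrainTests:
    def test_planted_strain_effect_detected(self, small_study):
        table, meta, truth = small_study
        rel = to_relative(table)
        pre_ids = [m.sample_id for m in meta if m.timepoint == "pre"]
        strain_of = {m.sample_id: m.strain for m in meta}
        res = baseline_strain_tests(rel.loc[pre_ids], strain_of,
                                    n_perm=999, seed=0)
        by_taxon = {r.taxon: r for r in res}
        planted = f"OTU_{truth.strain_effect_taxa[0]:04d}"
        assert by_taxon[planted].q < 0.05
        assert by_taxon[planted].direction == "B"  # higher in second strain


class TestBlockedRmAnova:
    @staticmethod
    def _null_relabund(seed, n_mice=6, n_taxa=5):
        rng = np.random.default_rng(seed)
        meta, rows, idx = [], [], []
        for s in ("BALB/c", "C57BL/6"):
            for t in ("CON", "AMP+NEO", "ERY"):
                for k in range(n_mice):
                    mouse = f"{s[:1]}{t[:1]}{k}"
                    for tp in ("pre", "post"):
                        sid = f"{mouse}_{tp}"
                        meta.append(SampleMeta(sid, mouse, s, t, tp))
                        rows.append(rng.uniform(size=n_taxa))
                        idx.append(sid)
        return pd.DataFrame(rows, index=idx), meta

    def test_identical_pre_post_gives_p_one(self):
        rel, meta = self._null_relabund(1)
        for m in meta:
            if m.timepoint == "post":
                rel.loc[m.sample_id] = \
                    rel.loc[m.sample_id.replace("post", "pre")]
        res = blocked_rm_permutation_anova(rel, meta, n_perm=99, seed=0)
        assert all(r.p_treatment_time == 1.0 for r in res)
        assert all(r.p_strain_treatment_time == 1.0 for r in res)

    def test_missing_timepoint_named(self):
        rel, meta = self._null_relabund(2)
        broken = [m for m in meta if m.sample_id != meta[0].sample_id]
        with pytest.raises(DataError, match=meta[0].mouse_id):
            blocked_rm_permutation_anova(rel.iloc[1:], broken, n_perm=9)

    def test_planted_effects_detected(self, small_study):
        table, meta, truth = small_study
        rel = to_relative(table)
        res = blocked_rm_permutation_anova(rel, meta, n_perm=999, seed=5)
        by_taxon = {r.taxon: r for r in res}
        tt_taxon = f"OTU_{truth.treatment_time_taxa[0][0]:04d}"
        tw_taxon = f"OTU_{truth.three_way_taxa[0]:04d}"
        assert by_taxon[tt_taxon].q_treatment_time < 0.05
        assert by_taxon[tw_taxon].q_strain_treatment_time < 0.05

    def test_blocking_preserves_mouse_multisets(self):
        # the permutation scheme only swaps pre/post within a mouse, so the
        # per-mouse pair {pre, post} is invariant: equivalently the permuted
        # statistic of a sign-flipped difference vector equals some
        # arrangement of within-mouse swaps. Check the sign-flip algebra:
        # flipping every mouse reproduces the observed F exactly.
        rel, meta = self._null_relabund(3, n_mice=2, n_taxa=1)
        res = blocked_rm_permutation_anova(rel, meta, n_perm=2 ** 12, seed=0)
        r = res[0]
        # exhaustive: global flip is one of the 2^12 arrangements, so the
        # observed F occurs at least twice -> p >= 2/4096
        assert r.p_treatment_time >= 2 / 4096
        assert r.p_strain_treatment_time >= 2 / 4096


class TestPosthoc:
    def test_posthoc_flags_planted_cell(self, small_study):
        table, meta, truth = small_study
        rel = to_relative(table)
        taxon = f"OTU_{truth.treatment_time_taxa[0][0]:04d}"
        df = posthoc_treatment_tests(rel, meta, taxa=[taxon],
                                     n_perm=4095, seed=0)
        hit = df[(df.treatment == "AMP+NEO") & (df.taxon == taxon)]
        assert (hit["p"] < 0.05).all()
        con = df[(df.treatment == "CON") & (df.taxon == taxon)]
        assert (con["p"] > 0.05).all()
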