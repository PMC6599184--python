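import numpy as np
import pytest
from scipy import stats

from gutmir.diversity import (
    alpha_diversity_curve,
    braycurtis,
    chao1,
    distance_matrix,
    multi_rarefaction_pcoa,
    pcoa,
    permanova,
    rarefy,
    shannon,
)
from gutmir.io import DataError


class TestRarefy:
    def test_depth_equals_total_returns_copy(self):
        v = np.array([3, 0, 7, 2])
        out = rarefy(v, 12, 0)
        np.testing.assert_array_equal(out, v)

    def test_depth_zero(self):
        assert rarefy(np.array([5, 5]), 0, 0).sum() == 0

    def test_sums_to_depth(self):
        rng = np.random.default_rng(1)
        v = rng.integers(0, 100, size=50)
        for d in (0, 10, int(v.sum()) // 2):
            assert rarefy(v, d, rng).sum() == d

    def test_hypergeometric_mean(self):
        # [1000,1000] at depth 1000: first component ~ Hypergeom(2000,1000,1000)
        rng = np.random.default_rng(7)
        draws = [rarefy(np.array([1000, 1000]), 1000, rng)[0]
                 for _ in range(500)]
        assert abs(np.mean(draws) - 500) < 25  # SD ~ 11.2, SE ~ 0.5

    def test_depth_exceeds_total_errors(self):
        with pytest.raises(DataError):
            rarefy(np.array([1, 1]), 3, 0)


class TestAlpha:
    def test_chao1_examples(self):
        assert chao1(np.array([5, 5, 5])) == 3.0
        assert chao1(np.array([1, 1, 2])) == 3.5
        assert chao1(np.array([1])) == 1.0
        assert chao1(np.array([0, 0])) == 0.0

    def test_chao1_lower_bounded_by_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = rng.integers(0, 5, size=30)
            s_obs = (v > 0).sum()
            est = chao1(v)
            assert est >= s_obs
            if (v == 1).sum() == 0:
                assert est == s_obs  # equality iff no singletons

    def test_shannon_examples(self):
        assert shannon(np.array([1, 1, 1, 1])) == pytest.approx(np.log(4))
        assert shannon(np.array([0, 9, 0])) == 0.0
        assert shannon(np.array([1, 3])) == pytest.approx(0.5623, abs=1e-4)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            v = rng.integers(1, 50, size=12)
            assert shannon(v) <= np.log((v > 0).sum()) + 1e-12

    def test_shannon_zero_sum_errors(self):
        with pytest.raises(DataError):
            shannon(np.array([0, 0]))


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert braycurtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert braycurtis([1, 0], [0, 4]) == 1.0
        assert braycurtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_binary_invariant_to_magnitude(self):
        a, b = np.array([5, 0, 2]), np.array([1, 1, 0])
        assert braycurtis(a, b, binary=True) == \
            braycurtis(a * 100, b * 7, binary=True)

    def test_range(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.integers(0, 10, 8)
            b = rng.integers(0, 10, 8)
            if (a + b).sum() == 0:
                continue
            assert 0.0 <= braycurtis(a, b) <= 1.0

    def test_both_zero_errors(self):
        with pytest.raises(DataError):
            braycurtis([0, 0], [0, 0])


class TestPcoa:
    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(D)
        rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=2)
        np.testing.assert_allclose(rec, D, atol=1e-9)
        # Euclidean input: no meaningful negative eigenvalues
        assert res.eigenvalues.min() > -1e-8 * res.eigenvalues.max()

    def test_pct_variance_monotone_and_sums_100(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(D)
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert (np.diff(res.pct_variance) <= 1e-9).all()

    def test_identical_points(self):
        D = np.zeros((3, 3))
        res = pcoa(D)
        assert res.coordinates.shape[1] == 0 or \
            np.allclose(res.coordinates, 0)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(DataError):
            pcoa(D)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 40, size=(7, 15))
        D = distance_matrix(counts)
        mine = pcoa(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D), method="eigh")
        k = min(3, mine.coordinates.shape[1])
        for ax in range(k):
            a = mine.coordinates[:, ax]
            b = theirs.samples.values[:, ax]
            assert abs(abs(np.corrcoef(a, b)[0, 1]) - 1) < 1e-6


class TestMultiRarefactionPcoa:
    def test_single_rarefaction_equals_plain_pcoa(self, small_study):
        table, _, _ = small_study
        summ = multi_rarefaction_pcoa(table, depth=11353, n_rarefactions=1,
                                      metric="braycurtis", seed=9)
        rng = np.random.default_rng(9)
        rare = np.stack([rarefy(c, 11353, rng) for c in table.counts])
        res = pcoa(distance_matrix(rare))
        np.testing.assert_allclose(
            summ.median_coordinates, res.coordinates[:, :2], atol=1e-12)
        np.testing.assert_allclose(summ.iqr_coordinates, 0, atol=1e-12)

    def test_low_depth_samples_excluded_not_silently(self, toy_table):
        with pytest.raises(DataError):
            # every toy sample is below depth -> fewer than 3 usable
            multi_rarefaction_pcoa(toy_table, depth=100, n_rarefactions=2)

    def test_strain_separation_on_planted_data(self, small_study):
        table, meta, _ = small_study
        summ = multi_rarefaction_pcoa(table, depth=11353, n_rarefactions=10,
                                      seed=2)
        strain = {m.sample_id: m.strain for m in meta}
        lab = np.array([strain[s] for s in summ.sample_ids])
        c = summ.median_coordinates
        g1 = c[lab == lab[0]].mean(axis=0)
        g2 = c[lab != lab[0]].mean(axis=0)
        sep = np.linalg.norm(g1 - g2)
        assert sep > np.median(summ.iqr_coordinates)


class TestPermanova:
    def test_separated_clusters_minimum_p(self):
        # clusters large enough that a random permutation recreating the
        # observed partition (which would tie the observed F) is negligible
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(12, 3))
        b = rng.normal(10, 0.1, size=(12, 3))
        pts = np.vstack([a, b])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        f, p = permanova(D, ["a"] * 12 + ["b"] * 12, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert f > 100

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        f1, _ = permanova(D, labels, n_perm=99, seed=0)
        perm = rng.permutation(10)
        f2, _ = permanova(D[np.ix_(perm, perm)], labels[perm],
                          n_perm=99, seed=0)
        assert f1 == pytest.approx(f2)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            pts = rng.normal(size=(8, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            _, p = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=199,
                             seed=int(rng.integers(2 ** 31)))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_skbio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(14)
        counts = rng.integers(0, 30, size=(10, 12))
        D = distance_matrix(counts)
        f, _ = permanova(D, ["a"] * 5 + ["b"] * 5, n_perm=9, seed=0)
        res = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D), ["a"] * 5 + ["b"] * 5, permutations=9)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(DataError):
            permanova(np.zeros((4, 4)), ["a"] * 4)


class TestAlphaCurve:
    def test_mean_curve_nondecreasing_in_depth(self, small_study):
        table, meta, _ = small_study
        curve = alpha_diversity_curve(table, depths=[1000, 2000, 5000],
                                      n_rarefactions=10, seed=0)
        for _, sub in curve.groupby("sample_id"):
            sub = sub.sort_values("depth")
            # within Monte-Carlo tolerance
            assert (np.diff(sub["chao1"]) > -2.0).all()
            assert (np.diff(sub["shannon"]) > -0.05).all()
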