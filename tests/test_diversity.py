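import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from phyconiche.diversity import (
    anosim,
    anova_lsd,
    beta_diversity,
    bray_curtis,
    chao1,
    goods_coverage,
    linear_fit,
    pcoa,
    rarefaction_curve,
    ruzicka,
    shannon,
    structure_correlation,
)


class TestShannon:
    def test_equal_abundances_give_log_k(self):
        for k in (2, 5, 13):
            assert shannon([10] * k) == pytest.approx(np.log(k))

    def test_single_otu_is_zero(self):
        assert shannon([42]) == 0.0

    def test_hand_computed_base2(self):
        assert shannon([4, 2, 2], base=2) == pytest.approx(1.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestChao1:
    def test_no_singletons_equals_observed_richness(self):
        assert chao1([5, 3, 2, 8]) == 4

    def test_hand_computed(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
        counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
        assert chao1(counts) == pytest.approx(14.0)

    def test_bias_corrected_when_no_doubletons(self):
        # F2=0, F1=3 -> S_obs + 3·2/2 = S_obs + 3
        counts = [1, 1, 1, 5, 5]
        assert chao1(counts) == pytest.approx(5 + 3)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chao1([1.5, 2])


class TestGoodsCoverage:
    def test_no_singletons(self):
        assert goods_coverage([2, 2, 5]) == 1.0

    def test_one_singleton_in_hundred(self):
        assert goods_coverage([1, 99]) == pytest.approx(0.99)

    def test_all_singletons(self):
        assert goods_coverage([1, 1, 1]) == 0.0


class TestRarefaction:
    def test_full_depth_recovers_full_metric(self):
        counts = [30, 20, 10]
        curve = rarefaction_curve(counts, [60], n_reps=3, seed=0)
        assert curve[60] == pytest.approx(shannon(counts))

    def test_richness_nondecreasing_in_depth(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 60, size=50)
        curve = rarefaction_curve(
            counts, [50, 200, 500, int(counts.sum())],
            n_reps=40, metric="richness", seed=7,
        )
        assert (np.diff(curve.to_numpy()) >= -1e-9).all()

    def test_seed_reproducible(self):
        counts = [30, 20, 10, 5]
        a = rarefaction_curve(counts, [20, 40], n_reps=5, seed=11)
        b = rarefaction_curve(counts, [20, 40], n_reps=5, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([3, 3], [100], seed=0)


class TestRuzicka:
    def test_identical_vectors(self):
        assert ruzicka([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert ruzicka([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_computed(self):
        assert ruzicka([2, 2], [1, 3]) == pytest.approx(0.4)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            ruzicka([0, 0], [0, 0])

    def test_bounds_and_identity_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.integers(0, 30, size=12)
            y = rng.integers(0, 30, size=12)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for fn in (ruzicka, bray_curtis):
                d = fn(x, y)
                assert 0.0 <= d <= 1.0
                assert fn(x, x) == 0.0
                assert d == pytest.approx(fn(y, x))


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(dist, [f"s{i}" for i in range(10)]))
        coords = res.samples.to_numpy()[:, :2]
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-8

    def test_identical_samples_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(d, ["a", "b", "c"]))
        coords = res.samples.to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_proportion_explained_bounded(self, random_table):
        res = pcoa(beta_diversity(random_table))
        assert res.proportion_explained.iloc[0] <= 1.0 + 1e-12


class TestAnosim:
    def _separated(self):
        # within-group distances all below every between-group distance
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.15],
                [0.8, 0.95, 0.15, 0.0],
            ]
        )
        return DistanceMatrix(d, ["a1", "a2", "b1", "b2"])

    def test_perfect_separation_gives_r_one(self):
        res = anosim(self._separated(), ["A", "A", "B", "B"], n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_skbio_r_statistic(self, random_table):
        dist = beta_diversity(random_table)
        groups = [random_table.stages[s] for s in dist.ids]
        ours = anosim(dist, groups, n_perm=99, seed=0)
        ref = skbio_anosim(dist, np.asarray(groups), permutations=0)
        assert ours.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0.2, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dist = DistanceMatrix(d, [f"s{i}" for i in range(8)])
        rs = [
            anosim(dist, rng.permutation(["A"] * 4 + ["B"] * 4), n_perm=1, seed=0).r
            for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_permutation_p_floor(self):
        res = anosim(self._separated(), ["A", "A", "B", "B"], n_perm=999, seed=1)
        assert res.p_value >= 1 / 1000

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            anosim(self._separated(), ["A", "A", "A", "B"], n_perm=9)


class TestAnovaLsd:
    def test_separated_constant_groups_extreme_p(self):
        rng = np.random.default_rng(2)
        values = np.r_[np.full(6, 1.0), np.full(6, 5.0)] + rng.normal(0, 1e-4, 12)
        res = anova_lsd(values, ["a"] * 6 + ["b"] * 6)
        assert res.p_value < 1e-6
        assert res.pairwise["significant"].all()

    def test_f_matches_hand_sums_of_squares(self):
        values = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 5.0, 4.0, 6.0])
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = anova_lsd(values, groups)
        grand = values.mean()
        ss_b = sum(3 * (values[groups == g].mean() - grand) ** 2 for g in "abc")
        ss_w = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
            for g in "abc"
        )
        assert res.f == pytest.approx((ss_b / 2) / (ss_w / 6))

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd([1, 2, 3], ["a", "a", "a"])


class TestLinearFit:
    def test_exact_line(self):
        fit = linear_fit([0, 1, 2, 3], [0, 2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_slope_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = [
            linear_fit(rng.normal(size=20), rng.normal(size=20)).p_value
            for _ in range(200)
        ]
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1, 2], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            linear_fit([1, 1, 1], [1, 2, 3])


class TestStructureCorrelation:
    def _dist(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.1, 1.0, size=(7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return DistanceMatrix(d, [f"s{i}" for i in range(7)])

    def test_self_correlation_is_one(self):
        d = self._dist(0)
        r, p = structure_correlation(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_independent_matrices_mean_r_near_zero(self):
        rs = [
            structure_correlation(self._dist(2 * k), self._dist(2 * k + 1),
                                  n_perm=1, seed=0)[0]
            for k in range(100)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_mismatched_ids_rejected(self):
        d1 = self._dist(0)
        d2 = DistanceMatrix(d1.data, [f"x{i}" for i in range(7)])
        with pytest.raises(ValueError, match="different samples"):
            structure_correlation(d1, d2)
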