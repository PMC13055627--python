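import numpy as np
import pytest
from scipy import stats as sps

from conftest import random_distance_matrix, table2_summaries
from hatrial.datamodel import GroupSummary
from hatrial.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientReplicationError,
    ValidationError,
)
from hatrial.stats import (
    anova_from_summary,
    anova_oneway,
    mantel,
    pearson_regression,
    rank_predictors,
    tukey_cld,
)


def summarize(groups):
    return [
        GroupSummary(f"g{i}", len(g), float(np.mean(g)), float(np.std(g, ddof=1)))
        for i, g in enumerate(groups)
    ]


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        groups = [np.array([1.0, 2.0, 3.0])] * 3
        res = anova_oneway(groups)
        assert res.F == 0 and res.p == 1

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        res = anova_oneway([a, b])
        t = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i, 1, 5) for i in range(4)]
        res = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_summary_route_equals_raw_route(self):
        # oracle equivalence to 1e-10 across 100 random fixtures
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [
                rng.normal(rng.normal(0, 2), rng.uniform(0.5, 2), int(rng.integers(2, 9)))
                for _ in range(k)
            ]
            raw = anova_oneway(groups)
            summ = anova_from_summary(summarize(groups))
            assert summ.F == pytest.approx(raw.F, abs=1e-10)
            assert summ.p == pytest.approx(raw.p, abs=1e-10)
            assert (summ.df_between, summ.df_within) == (raw.df_between, raw.df_within)

    def test_published_yield_component_table(self):
        res = anova_from_summary(table2_summaries("thousand_grain_weight"))
        assert res.p == pytest.approx(0.100, abs=0.01)  # table prints 0.100
        assert res.F == pytest.approx(2.97, abs=0.01)
        assert anova_from_summary(table2_summaries("spike_number")).p < 0.001
        assert anova_from_summary(table2_summaries("grain_number")).p <= 0.001

    def test_equal_means_any_sds(self):
        res = anova_from_summary(
            [GroupSummary("a", 3, 5.0, 1.0), GroupSummary("b", 3, 5.0, 2.0)]
        )
        assert res.F == 0 and res.p == 1

    def test_zero_within_variance_flagged(self):
        res = anova_from_summary(
            [GroupSummary("a", 3, 1.0, 0.0), GroupSummary("b", 3, 2.0, 0.0)]
        )
        assert res.flagged and 0 < res.p < 1e-100

    def test_singleton_group_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            anova_oneway([np.array([1.0]), np.array([1.0, 2.0])])


class TestTukeyCLD:
    @pytest.mark.parametrize(
        "component,expected",
        [
            ("spike_number", {"CK": "c", "HA3": "b", "HA7.5": "ab", "HA15": "a"}),
            ("grain_number", {"CK": "b", "HA3": "b", "HA7.5": "a", "HA15": "a"}),
            ("thousand_grain_weight",
             {"CK": "a", "HA3": "a", "HA7.5": "a", "HA15": "a"}),
        ],
    )
    def test_reproduces_published_letters(self, component, expected):
        cld = tukey_cld(table2_summaries(component), alpha=0.05)
        assert cld.letters == expected

    def test_identical_groups_share_one_letter(self):
        groups = [GroupSummary(g, 3, 5.0, 1.0) for g in "abcd"]
        cld = tukey_cld(groups)
        assert set(cld.letters.values()) == {"a"}

    def test_partition_invariant_to_input_order(self):
        summaries = table2_summaries("spike_number")
        forward = tukey_cld(summaries).letters
        backward = tukey_cld(summaries[::-1]).letters
        assert forward == backward

    def test_letter_a_goes_to_largest_mean(self):
        summaries = table2_summaries("grain_number")
        cld = tukey_cld(summaries)
        best = max(summaries, key=lambda s: s.mean)
        assert "a" in cld.letters[best.group]

    def test_zero_pooled_variance_warns_and_separates(self):
        groups = [GroupSummary("a", 3, 1.0, 0.0), GroupSummary("b", 3, 2.0, 0.0)]
        with pytest.warns(UserWarning):
            cld = tukey_cld(groups)
        assert cld.letters["a"] != cld.letters["b"]

    def test_matches_statsmodels_on_raw_data(self):
        # reconstruct raw groups with exact summary stats, compare the
        # significance pattern with statsmodels' Tukey HSD
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(5)
        groups = [rng.normal(i * 0.8, 1, 6) for i in range(4)]
        summaries = summarize(groups)
        cld = tukey_cld(summaries)
        values = np.concatenate(groups)
        labels = np.repeat([s.group for s in summaries], [len(g) for g in groups])
        ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
        rejects = ref.reject
        pairs = [
            (summaries[i].group, summaries[j].group)
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        for (a, b), reject in zip(pairs, rejects):
            shared = set(cld.letters[a]) & set(cld.letters[b])
            assert bool(shared) == (not reject)


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        res = pearson_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2)
        assert res.intercept == pytest.approx(1)
        assert res.r == pytest.approx(1)

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3])
        assert pearson_regression(x, -x).r == pytest.approx(-1)

    def test_hand_computed_five_points(self):
        # hand sums: Sxx = 10, Sxy = 10, Syy = 14.8
        # slope = Sxy/Sxx = 1.0; r = Sxy/sqrt(Sxx*Syy) = 10/sqrt(148)
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        res = pearson_regression(x, y)
        assert res.r == pytest.approx(10 / np.sqrt(148), abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_is_explained_variance_share(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        res = pearson_regression(x, y)
        fitted = res.slope * x + res.intercept
        ss_reg = ((fitted - y.mean()) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert res.r**2 == pytest.approx(ss_reg / ss_tot, abs=1e-10)

    def test_band_narrowest_at_mean_x(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 20)
        y = x + rng.normal(size=20)
        res = pearson_regression(x, y)
        grid = np.linspace(x.min(), x.max(), 101)
        widths = res.ci_halfwidth(grid)
        # narrowest at the mean of x, widening monotonically on both sides
        assert res.ci_halfwidth(res.x_mean) <= widths.min() + 1e-12
        assert (np.diff(widths[grid >= res.x_mean]) >= -1e-12).all()
        assert (np.diff(widths[grid <= res.x_mean]) <= 1e-12).all()

    def test_constant_inputs_rejected(self):
        with pytest.raises(DomainError):
            pearson_regression([1.0, 1, 1], [1.0, 2, 3])
        with pytest.raises(DegenerateInputError):
            pearson_regression([1.0, 2, 3], [1.0, 1, 1])


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(0)
        d = random_distance_matrix(rng, 8)
        res = mantel(d, d, n_permutations=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_constant_matrix_rejected(self):
        d = 1 - np.eye(5)
        other = random_distance_matrix(np.random.default_rng(0), 5)
        with pytest.raises(DegenerateInputError):
            mantel(other, d)

    @pytest.mark.parametrize(
        "bad",
        [
            np.arange(16, dtype=float).reshape(4, 4),  # asymmetric
            np.eye(4),                                  # nonzero diagonal
        ],
    )
    def test_invalid_matrix_rejected(self, bad):
        good = random_distance_matrix(np.random.default_rng(1), 4)
        with pytest.raises(ValidationError):
            mantel(good, bad)

    def test_seeded_and_reproducible(self):
        rng = np.random.default_rng(2)
        d1 = random_distance_matrix(rng, 9)
        d2 = random_distance_matrix(rng, 9)
        a = mantel(d1, d2, seed=11)
        b = mantel(d1, d2, seed=11)
        assert (a.r, a.p) == (b.r, b.p)

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(3)
        d1 = random_distance_matrix(rng, 10)
        d2 = random_distance_matrix(rng, 10)
        perm = rng.permutation(10)
        a = mantel(d1, d2, n_permutations=9999, seed=5)
        b = mantel(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)],
                   n_permutations=9999, seed=5)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        # the exhaustive-permutation p is exactly invariant; the sampled p
        # fluctuates with SE ~ sqrt(p(1-p)/B), so compare at ~4 sigma
        se = np.sqrt(2 * a.p * (1 - a.p) / 9999)
        assert abs(a.p - b.p) < 4 * se

    def test_r_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(4)
        d1 = random_distance_matrix(rng, 8)
        d2 = random_distance_matrix(rng, 8)
        ours = mantel(d1, d2, n_permutations=999, seed=0)
        ref_r, _, _ = skbio_mantel(
            DistanceMatrix(d1), DistanceMatrix(d2), permutations=0
        )
        assert ours.r == pytest.approx(ref_r, abs=1e-12)

    def test_positive_association_detected(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform

        d1 = squareform(pdist(pts))
        d2 = squareform(pdist(pts + rng.normal(0, 0.05, pts.shape)))
        res = mantel(d1, d2, seed=0)
        assert res.r > 0.8 and res.p < 0.01


class TestRankPredictors:
    def make_data(self, seed, n=40):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = X[:, 0] + 0.01 * rng.normal(size=n)
        return X, y

    def test_signal_feature_ranked_first_and_significant(self):
        hits = 0
        for seed in range(10):
            X, y = self.make_data(seed)
            ranking = rank_predictors(
                X, y, feature_names=["A", "B", "C"], n_permutations=49, seed=seed
            )
            name, _, p = ranking.ranked_features[0]
            if name == "A" and p <= 0.05:
                hits += 1
        assert hits == 10

    def test_importances_descending_and_p_in_unit_interval(self):
        X, y = self.make_data(0)
        ranking = rank_predictors(X, y, n_permutations=29, seed=0)
        imps = [imp for _, imp, _ in ranking.ranked_features]
        assert imps == sorted(imps, reverse=True)
        assert all(0 < p <= 1 for _, _, p in ranking.ranked_features)

    def test_duplicate_features_share_importance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = np.column_stack([a, a, rng.normal(size=50)])
        y = a + 0.05 * rng.normal(size=50)
        ranking = rank_predictors(
            X, y, feature_names=["A1", "A2", "noise"], n_permutations=19, seed=2
        )
        imp = {name: v for name, v, _ in ranking.ranked_features}
        assert abs(imp["A1"] - imp["A2"]) < 0.25
        assert imp["noise"] < min(imp["A1"], imp["A2"])

    def test_deterministic_under_fixed_seed(self):
        X, y = self.make_data(3)
        a = rank_predictors(X, y, n_permutations=19, seed=9)
        b = rank_predictors(X, y, n_permutations=19, seed=9)
        assert a == b

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DegenerateInputError):
            rank_predictors(X, np.ones(10))
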