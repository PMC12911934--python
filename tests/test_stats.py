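import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_cliffs
from magfred.exceptions import UndefinedStatisticError, ValidationError
from magfred.stats import (
    build_design,
    cliffs_delta,
    community_weighted_mean,
    fit_fred_model,
    group_contrast,
    pearson_correlation,
    permanova,
    wilcoxon_rank_sum,
)


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_small_sample(self):
        # all 6 rank assignments of {1,2} vs {3,4}: two-sided p = 2/6
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_rank_sum_statistic(self):
        w, _ = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert w == 3.0  # ranks 1 + 2

    def test_exact_vs_asymptotic_agreement(self):
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            exact = scipy.stats.mannwhitneyu(x, y, method="exact").pvalue
            approx = scipy.stats.mannwhitneyu(x, y, method="asymptotic",
                                              use_continuity=True).pvalue
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.02

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_ties_use_midranks(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0])
        assert w == pytest.approx(1 + 3 + 3)
        assert 0 < p <= 1


class TestCliffsDelta:
    def test_complete_separation(self):
        assert cliffs_delta([3.0, 4.0], [1.0, 2.0]) == 1.0
        assert cliffs_delta([1.0, 2.0], [3.0, 4.0]) == -1.0

    def test_identical_groups(self):
        assert cliffs_delta([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_counted(self):
        assert cliffs_delta([1.0, 3.0], [2.0, 2.0]) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            x = rng.integers(0, 10, size=rng.integers(1, 12)).astype(float)
            y = rng.integers(0, 10, size=rng.integers(1, 12)).astype(float)
            assert cliffs_delta(x, y) == brute_force_cliffs(x, y)

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=15),
           st.lists(st.integers(-5, 5), min_size=1, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_property_matches_oracle(self, x, y):
        assert cliffs_delta(x, y) == brute_force_cliffs(x, y)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, r2, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson_correlation(x, y)[0] == pytest.approx(pearson_correlation(y, x)[0])

    def test_independent_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        r, _, _ = pearson_correlation(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_error(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFitFredModel:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(4)
        temp = pd.Series(rng.uniform(5, 30, 30), name="temperature")
        fred = pd.Series(0.5 + 0.01 * temp.to_numpy(), name="FRed",
                         index=temp.index)
        fit = fit_fred_model(fred, temp.to_frame())
        assert fit.coefficients["temperature"] == pytest.approx(0.01, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_two_point_closed_form(self):
        fred = pd.Series([1.0, 3.0], name="FRed")
        x = pd.DataFrame({"x": [0.0, 2.0]})
        fit = fit_fred_model(fred, x)
        assert fit.coefficients["x"] == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["const"] == pytest.approx(1.0, abs=1e-12)

    def test_collinearity_screen(self, caplog):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 25)
        design = pd.DataFrame({"a": x, "dup": x * 2.0 + 1e-9 * rng.normal(size=25),
                               "b": rng.uniform(0, 1, 25)})
        fred = pd.Series(x + rng.normal(0, 0.01, 25), name="FRed")
        with caplog.at_level("WARNING"):
            fit = fit_fred_model(fred, design)
        assert "dup" in fit.dropped_collinear
        assert "dup" not in fit.terms

    def test_categorical_dummy_coding(self):
        design = pd.DataFrame({"season": ["spring"] * 5 + ["summer"] * 5,
                               "temperature": np.arange(10.0)})
        fred = pd.Series(np.r_[np.zeros(5), np.ones(5)]
                         + 0.001 * np.arange(10), name="FRed")
        fit = fit_fred_model(fred, design, reference_levels={"season": "spring"})
        assert "season[summer]" in fit.terms

    def test_adjusted_r2_bound(self):
        rng = np.random.default_rng(6)
        design = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        fred = pd.Series(rng.normal(size=40), name="FRed")
        fit = fit_fred_model(fred, design)
        assert fit.adjusted_r2 <= fit.r2 <= 1.0

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            design = pd.DataFrame({"a": rng.normal(size=25)})
            fred = pd.Series(rng.normal(size=25), name="FRed")
            pvals.append(fit_fred_model(fred, design).p)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_listwise_missing(self):
        design = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]})
        fred = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], name="FRed")
        fit = fit_fred_model(fred, design)
        assert fit.n == 5


def _two_group_distance(rng, n_per_group, shift=0.0):
    a = rng.normal(0, 1, size=(n_per_group, 3))
    b = rng.normal(shift, 1, size=(n_per_group, 3))
    pts = np.vstack([a, b])
    from scipy.spatial.distance import pdist, squareform
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=ids)
    return d, groups


class TestPermanova:
    def test_p_lower_bound(self):
        rng = np.random.default_rng(8)
        d, groups = _two_group_distance(rng, 6, shift=10.0)
        res = permanova(d, groups, n_permutations=99, seed=1)
        assert res.p >= 1.0 / 100.0
        assert res.pseudo_f > 1.0
        assert 0.0 <= res.r2 <= 1.0

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(9)
        d, groups = _two_group_distance(rng, 8, shift=8.0)
        res = permanova(d, groups, n_permutations=199, seed=2)
        assert res.p <= 0.01

    def test_null_not_significant(self):
        rng = np.random.default_rng(10)
        hits = 0
        for rep in range(20):
            d, groups = _two_group_distance(rng, 6, shift=0.0)
            res = permanova(d, groups, n_permutations=99, seed=rep)
            hits += res.p <= 0.05
        assert hits <= 4

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        d, groups = _two_group_distance(rng, 5, shift=1.0)
        res1 = permanova(d, groups, n_permutations=99, seed=3)
        order = rng.permutation(len(groups))
        ids = d.index.to_numpy()[order]
        res2 = permanova(d.loc[ids, ids], groups.loc[ids], n_permutations=99, seed=3)
        assert res2.p == res1.p
        assert res2.pseudo_f == pytest.approx(res1.pseudo_f, abs=1e-12)

    def test_single_group_is_error(self):
        rng = np.random.default_rng(12)
        d, groups = _two_group_distance(rng, 4)
        with pytest.raises(ValidationError):
            permanova(d, pd.Series(["A"] * len(groups), index=groups.index),
                      n_permutations=99, seed=1)

    def test_seed_required(self):
        rng = np.random.default_rng(13)
        d, groups = _two_group_distance(rng, 4)
        with pytest.raises(ValidationError, match="seed"):
            permanova(d, groups)

    def test_multi_term_design(self):
        rng = np.random.default_rng(14)
        d, groups = _two_group_distance(rng, 6, shift=3.0)
        design = pd.DataFrame({"group": groups,
                               "cov": rng.normal(size=len(groups))}, index=groups.index)
        res = permanova(d, design, n_permutations=99, seed=4)
        assert res.df_model == 2


class TestGroupContrast:
    def test_direction_and_fields(self):
        values = pd.Series([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["A", "A", "A", "B", "B", "B"])
        c = group_contrast(values, groups, "A", "B")
        assert c.delta == 1.0
        assert c.n_a == c.n_b == 3
        assert c.p < 0.2


class TestCommunityWeightedMean:
    def test_weighted_average(self):
        table = pd.DataFrame([[0.0], [10.0]], index=["m1", "m2"], columns=["t"])
        ab = pd.DataFrame({"m1": [3.0, 1.0], "m2": [1.0, 3.0]}, index=["s1", "s2"])
        cwm = community_weighted_mean(table, ab)
        assert cwm.loc["s1", "t"] == pytest.approx(2.5)
        assert cwm.loc["s2", "t"] == pytest.approx(7.5)


class TestBuildDesign:
    def test_reference_level_omitted(self):
        design = build_design(pd.DataFrame({"season": ["spring", "summer", "spring"]}),
                              {"season": "spring"})
        assert list(design.columns) == ["season[summer]"]
        assert design["season[summer]"].tolist() == [0.0, 1.0, 0.0]
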