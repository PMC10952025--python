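"""Unit and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernapipe.errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)
from cernapipe.stats import (
    associate_feature,
    bh_adjust,
    hypergeom_enrich,
    pairwise_pearson,
    pearson_test,
    spearman_test,
    welch_anova,
    welch_t,
)


def brute_force_bh_rejections(p, q):
    """Independent step-up oracle: largest k with p_(k) <= q*k/m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_rejection_sets_match_step_up_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            adj = bh_adjust(p)
            for q in (0.01, 0.05, 0.1, 0.25, rng.uniform()):
                np.testing.assert_array_equal(
                    adj <= q, brute_force_bh_rejections(p, q),
                    err_msg=f"q={q} p={p}",
                )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(ref)

    def test_rejects_out_of_range(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bounds_property(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed(self):
        # s^2 = 1 in each group, se = sqrt(2/3), t = -3/se
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert abs(res.statistic) == pytest.approx(3.674, abs=1e-3)
        assert res.df == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0214, abs=1e-3)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateDataError):
            welch_t([0, 0], [1, 1])

    def test_too_small_group(self):
        with pytest.raises(InsufficientDataError):
            welch_t([1], [2, 3])

    def test_anova_identical_groups(self):
        res = welch_anova([[1, 2, 3]] * 3)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_anova_equals_t_squared_for_two_groups(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 15)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 15)))
            t = welch_t(a, b)
            f = welch_anova([a, b])
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
            assert f.df[1] == pytest.approx(t.df, rel=1e-10)

    def test_anova_planted_shift(self, rng):
        groups = [rng.normal(3 * i, 1, 20) for i in range(3)]
        assert welch_anova(groups).p_value < 1e-3

    def test_anova_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        data = [rng.normal(i * 0.4, 1 + i, 15) for i in range(4)]
        mine = welch_anova(data)
        df = pd.DataFrame(
            {"y": np.concatenate(data), "g": np.repeat(range(4), 15)}
        )
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert mine.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert mine.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_anova_needs_two_groups(self):
        with pytest.raises(InvalidInputError):
            welch_anova([[1, 2, 3]])


class TestCorrelation:
    def test_pearson_exact_linearity(self):
        assert pearson_test([1, 2, 3], [2, 4, 6]).coefficient == pytest.approx(1.0)
        assert pearson_test([1, 2, 3], [-1, -2, -3]).coefficient == pytest.approx(-1.0)

    def test_pearson_null_small(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(pearson_test(x, y).coefficient) < 0.1

    def test_pearson_affine_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = pearson_test(x, y)
        scaled = pearson_test(3 * x + 1, 0.5 * y - 7)
        assert scaled.coefficient == pytest.approx(base.coefficient)
        assert scaled.p_value == pytest.approx(base.p_value)

    def test_pearson_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_spearman_monotone_invariance(self, rng):
        x = np.sort(rng.normal(size=20))
        assert spearman_test(x, np.exp(x)).coefficient == pytest.approx(1.0)
        assert spearman_test(x, x[::-1]).coefficient == pytest.approx(-1.0)

    def test_spearman_midrank_ties(self):
        res = spearman_test([1, 1, 2, 3], [2, 2, 4, 9])
        assert res.coefficient == pytest.approx(1.0)

    def test_spearman_exact_p_small_n(self):
        # perfect monotone with n=4: only 1 of 24 permutations as extreme
        # per tail -> two-sided p = 2/24
        res = spearman_test([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.p_value == pytest.approx(2 / 24)

    def test_spearman_approx_matches_scipy_large_n(self, rng):
        from scipy import stats as sps

        x, y = rng.normal(size=50), rng.normal(size=50)
        mine = spearman_test(x, y)
        rho, _ = sps.spearmanr(x, y)
        assert mine.coefficient == pytest.approx(rho)

    def test_pairwise_pearson_agrees_with_scalar(self, rng):
        x = rng.normal(size=(4, 25))
        y = rng.normal(size=(3, 25))
        r, p = pairwise_pearson(x, y)
        for i in range(4):
            for j in range(3):
                ref = pearson_test(x[i], y[j])
                assert r[i, j] == pytest.approx(ref.coefficient)
                assert p[i, j] == pytest.approx(ref.p_value)


class TestHypergeom:
    def test_direct_enumeration_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_enrich(4, 4, 5, 10).p_value == pytest.approx(5 / 210)

    def test_trivial_tails(self):
        assert hypergeom_enrich(0, 4, 5, 10).p_value == pytest.approx(1.0)
        assert hypergeom_enrich(6, 6, 6, 6).p_value == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(InvalidInputError):
            hypergeom_enrich(5, 4, 5, 10)
        with pytest.raises(InvalidInputError):
            hypergeom_enrich(1, 4, 11, 10)

    def test_exhaustive_enumeration_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            universe = range(N)
            hits = set(range(K))
            count = sum(
                1
                for draw in itertools.combinations(universe, n)
                if len(hits.intersection(draw)) >= k
            )
            expected = count / math.comb(N, n)
            assert hypergeom_enrich(k, n, K, N).p_value == pytest.approx(expected)


class TestAssociateFeature:
    def test_dispatches_welch_t_for_binary(self, rng):
        res = associate_feature(rng.normal(size=20), ["a"] * 10 + ["b"] * 10)
        assert res.method == "welch_t"

    def test_dispatches_anova_for_multilevel(self, rng):
        labels = ["I", "II", "III", "IV"] * 5
        res = associate_feature(rng.normal(size=20), labels)
        assert res.method == "welch_anova"

    def test_missing_labels_dropped(self, rng):
        labels = ["a"] * 8 + ["b"] * 8 + [None] * 4
        res = associate_feature(rng.normal(size=20), labels)
        assert res.details["n"] == 16
        assert res.details["n_dropped"] == 4

    def test_single_level_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            associate_feature(rng.normal(size=6), ["x"] * 6)
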