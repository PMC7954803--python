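"""Statistics layer tests.

Frozen reference values in this module were computed with R 4.3
(``shapiro.test``, ``t.test(paired=TRUE)``, ``wilcox.test(paired=TRUE,
exact=TRUE)`` and ``car::Anova`` with a Geisser–Greenhouse-corrected
repeated-measures design) on the exact numbers listed here.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histoconcord.cohort_stats import (
    _friedman_dunn,
    _rm_anova_gg,
    compare_many,
    compare_two,
    normality_gate,
    summarize,
    wilcoxon_exact,
)

X = np.array([8.021757, 9.264427, 12.575851, 10.387949, 11.840462,
              11.154208, 8.727073, 11.083904, 9.366809, 9.355222])
Y = np.array([8.918924, 8.538497, 14.568017, 10.516859, 13.640731,
              12.090529, 11.059106, 11.223935, 9.855014, 10.492991])
MIX = np.array([-0.003618, -0.012302, 0.012262, 9.97828, -0.003701,
                0.001644, 0.008599, 10.017617, 10.009933, 9.997085])
MAT = np.array(
    [
        [5.728128, 4.2384, 7.429939],
        [4.843525, 4.826241, 5.36094],
        [4.938639, 5.107215, 8.28991],
        [4.281819, 5.532608, 6.02805],
        [5.028272, 5.555346, 5.518437],
        [4.416592, 4.637839, 4.511825],
        [5.216307, 6.484376, 5.456916],
        [4.441385, 5.183517, 5.53936],
    ]
)


def wilcoxon_by_enumeration(d):
    """Exact two-sided signed-rank p by brute force over all sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_low, p_high))


class TestNormalityGate:
    def test_normal_sample_matches_r_reference(self):
        v = normality_gate(X)
        assert v.normal
        assert v.p_value == pytest.approx(0.7643036821, abs=1e-6)

    def test_two_point_mixture_rejected(self):
        v = normality_gate(MIX)
        assert not v.normal
        assert v.p_value == pytest.approx(0.0001779595, abs=1e-6)

    def test_constant_vector_degenerate_non_normal(self):
        with pytest.warns(UserWarning):
            v = normality_gate([2.0] * 10)
        assert v.degenerate and not v.normal

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestWilcoxonExact:
    def test_uniform_sign_n5_is_exactly_2_over_32(self):
        w, p = wilcoxon_exact([1.0, 2.0, 3.0, 4.0, 5.0])
        assert w == 15.0
        assert p == 0.0625

    def test_paired_example_matches_r(self):
        _, p = wilcoxon_exact(X - Y)
        assert p == pytest.approx(0.013671875, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_full_enumeration_with_and_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        d = rng.integers(-4, 5, size=n).astype(float)  # many ties, some zeros
        if np.all(d == 0):
            d[0] = 1.0
        _, p = wilcoxon_exact(d)
        assert p == pytest.approx(wilcoxon_by_enumeration(d), abs=1e-12)

    def test_tie_free_case_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, 12)
        _, p = wilcoxon_exact(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)


class TestCompareTwo:
    def _table(self, a, b):
        return pd.DataFrame({"A": a, "B": b})

    def test_identical_conditions_degenerate(self):
        rep = compare_two(self._table(X, X), "A", "B")
        assert rep.degenerate and rep.p_value == 1.0 and not rep.significant

    def test_normal_differences_take_paired_t_matching_r(self):
        rep = compare_two(self._table(X, Y), "A", "B")
        assert "paired t" in rep.test
        assert rep.statistic == pytest.approx(-3.0431336482, abs=1e-6)
        assert rep.p_value == pytest.approx(0.0139469944, abs=1e-6)

    def test_non_normal_differences_take_wilcoxon(self):
        a = np.concatenate([np.zeros(6), np.full(4, 10.0)]) + np.arange(10) * 1e-3
        b = a + MIX
        rep = compare_two(self._table(a, b), "A", "B")
        assert "Wilcoxon" in rep.test

    def test_missing_values_complete_case_deletion(self):
        a = list(X)
        b = list(Y)
        a[0] = np.nan
        rep = compare_two(self._table(a, b), "A", "B")
        assert rep.n == 9

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_two(self._table([1, 2], [2, 3]), "A", "B")


class TestCompareMany:
    def test_identical_conditions_degenerate(self):
        t = pd.DataFrame({"a": X, "b": X, "c": X})
        rep = compare_many(t, ["a", "b", "c"])
        assert rep.degenerate and rep.p_value == 1.0

    def test_friedman_statistic_matches_hand_computation(self):
        # 4 patients x 3 conditions, no ties; chi-square form:
        # Q = 12/(n k (k+1)) * sum Rj^2 - 3 n (k+1)
        tbl = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0], [1.0, 2.0, 3.0]])
        stat, p, posthoc = _friedman_dunn(tbl, ["a", "b", "c"], 0.05)
        ranks = np.array([stats.rankdata(r) for r in tbl])
        col_sums = ranks.sum(axis=0)
        n, k = tbl.shape
        hand = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3 * n * (k + 1)
        assert stat == pytest.approx(hand)
        assert len(posthoc) == 3 and all(p.test.startswith("Dunn") for p in posthoc)

    def test_friedman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(7, 3)) + [0, 0.5, 1.0]
        s1, _, _ = _friedman_dunn(x, list("abc"), 0.05)
        s2, _, _ = _friedman_dunn(np.exp(x), list("abc"), 0.05)
        assert s1 == pytest.approx(s2)

    def test_gg_anova_matches_r_car_reference(self):
        f, p_gg, posthoc = _rm_anova_gg(MAT, ["c1", "c2", "c3"], 0.05)
        assert p_gg == pytest.approx(0.06795688, abs=1e-6)
        assert len(posthoc) == 3 and all(p.test == "Fisher LSD" for p in posthoc)

    def test_normal_matrix_routes_to_rm_anova(self):
        rep = compare_many(
            pd.DataFrame(MAT, columns=["c1", "c2", "c3"]), ["c1", "c2", "c3"]
        )
        assert "ANOVA" in rep.test
        assert rep.p_value == pytest.approx(0.06795688, abs=1e-6)

    def test_dunn_z_is_zero_for_equal_mean_ranks(self):
        tbl = np.array(
            [[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [3.0, 1.0, 2.0]]
        )  # latin square: equal rank sums
        _, _, posthoc = _friedman_dunn(tbl, list("abc"), 0.05)
        for c in posthoc:
            assert c.statistic == pytest.approx(0.0)
            assert c.p_value == pytest.approx(1.0)


class TestSummarize:
    def test_odd_sample_median(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.median == 3 and s.min == 1 and s.max == 5

    def test_linear_interpolation_percentiles(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=23)
        s = summarize(v)
        assert s.q25 == pytest.approx(np.percentile(v, 25))
        assert s.q75 == pytest.approx(np.percentile(v, 75))

    def test_single_value_degenerate_iqr(self):
        s = summarize([7.0])
        assert s.median == s.q25 == s.q75 == 7.0

    def test_missing_dropped_and_empty_is_none(self):
        assert summarize([np.nan, 1.0, np.nan]).n == 1
        assert summarize([np.nan, np.nan]) is None
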