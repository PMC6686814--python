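"""Exact Mann-Whitney and Benjamini-Hochberg against independent oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivdkit.stats import apply_bh, benjamini_hochberg, mann_whitney_u


def brute_force_two_sided_p(x, y):
    """Permutation oracle using the pair-count definition of U.

    Independent of the implementation's rank-sum route: U is counted as
    #(x_i > y_j) + 0.5 * #(x_i == y_j), enumerated over every allocation of
    the pooled values.
    """
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)

    def u_of(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(x, y)
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        u = u_of(xs, ys)
        lo += u <= u_obs + 1e-9
        hi += u >= u_obs - 1e-9
        total += 1
    return min(1.0, 2 * min(lo, hi) / total)


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "exact"

    def test_identical_multisets_give_p_one(self):
        r = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert r.p_value == 1.0

    def test_degenerate_constant_samples_flagged(self):
        r = mann_whitney_u([5, 5, 5], [5, 5])
        assert r.p_value == 1.0
        assert r.method == "degenerate"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        # random instances (with ties) covering n1*n2 <= 36
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            x[0] += 1
        r = mann_whitney_u(x, y)
        assert r.p_value == pytest.approx(brute_force_two_sided_p(list(x), list(y)))

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(1.0, size=30)
        r = mann_whitney_u(x, y)
        assert r.method == "normal_approx"
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_exact_test_type_one_error_is_conservative(self):
        # under the null (n=6 vs 6), rejection rate at alpha=0.05 stays <= 0.05
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(size=6), rng.normal(size=6)
            rejections += mann_whitney_u(x, y).p_value <= 0.05
        assert rejections / reps <= 0.05


class TestBenjaminiHochberg:
    def test_single_p_value(self):
        r = benjamini_hochberg([0.01], alpha=0.05)
        assert r.reject.tolist() == [True]
        assert r.adjusted_p[0] == pytest.approx(0.01)

    def test_four_value_step_up(self):
        # thresholds k*alpha/m = .0125, .025, .0375, .05:
        # 0.04 > 0.0375, so the step-up stops at k = 2
        r = benjamini_hochberg([0.01, 0.02, 0.04, 0.30], alpha=0.05)
        assert r.reject.tolist() == [True, True, False, False]
        assert r.n_rejected == 2
        assert r.corrected_threshold == pytest.approx(0.02)
        np.testing.assert_allclose(
            r.adjusted_p, [0.04, 0.04, 0.04 * 4 / 3, 0.30], rtol=1e-12
        )

    def test_all_ones_reject_nothing(self):
        r = benjamini_hochberg([1.0, 1.0, 1.0])
        assert r.n_rejected == 0
        assert r.corrected_threshold is None

    def test_empty_input(self):
        assert benjamini_hochberg([]).n_rejected == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        ours = benjamini_hochberg(p, alpha=0.05)
        rej, adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(ours.adjusted_p, adj, rtol=1e-12)
        np.testing.assert_array_equal(ours.reject, rej)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        st.floats(0.01, 0.2),
    )
    def test_bh_between_bonferroni_and_unadjusted(self, p, alpha):
        bh = benjamini_hochberg(p, alpha=alpha)
        p_arr = np.asarray(p)
        n_unadjusted = int(np.sum(p_arr <= alpha))
        n_bonferroni = int(np.sum(p_arr <= alpha / len(p)))
        assert n_bonferroni <= bh.n_rejected <= n_unadjusted
        # adjusted p's respect ordering of raw p's
        order = np.argsort(p_arr)
        assert np.all(np.diff(bh.adjusted_p[order]) >= -1e-12)

    def test_rejections_monotone_in_alpha(self):
        p = [0.001, 0.011, 0.02, 0.08, 0.3, 0.9]
        counts = [benjamini_hochberg(p, alpha=a).n_rejected for a in (0.01, 0.05, 0.1, 0.25)]
        assert counts == sorted(counts)


class TestApplyBh:
    def test_annotates_comparisons(self):
        comps = [
            mann_whitney_u([1, 2, 3], [4, 5, 6], endpoint="a"),
            mann_whitney_u([1, 2, 3], [1, 2, 3], endpoint="b"),
        ]
        out = apply_bh(comps, alpha=0.2)
        assert out[0].bh_adjusted_p == pytest.approx(0.2)
        assert out[0].significant
        assert not out[1].significant
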