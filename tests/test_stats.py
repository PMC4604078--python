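"""Unit and property tests for the statistical kernels and decision tree."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from dystromorph import stats as st


class TestAnalyticKernels:
    def test_t_of_zero_is_one(self):
        assert st.p_from_t(0.0, 5) == pytest.approx(1.0)

    def test_t_requires_valid_df(self):
        with pytest.raises(st.StatError):
            st.p_from_t(1.0, 0)

    def test_p_monotone_in_statistic(self):
        ts = np.linspace(0, 6, 30)
        ps = [st.p_from_t(t, 9) for t in ts]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        fs = np.linspace(0, 30, 30)
        pf = [st.p_from_f(f, 2, 9) for f in fs]
        assert all(a > b for a, b in zip(pf, pf[1:]))

    def test_f_zero_is_one(self):
        assert st.p_from_f(0.0, 2, 10) == pytest.approx(1.0)

    def test_f_df1_2_closed_form(self):
        # for df1=2 the upper tail is (1 + 2F/df2)^(-df2/2)
        for f, df2 in [(5.52, 8), (0.7, 11), (12.3, 4)]:
            assert st.p_from_f(f, 2, df2) == pytest.approx(
                (1 + 2 * f / df2) ** (-df2 / 2), abs=1e-10)

    def test_kruskal_df2_closed_form(self):
        for h in (0.5, 7.73, 15.0):
            assert st.p_from_chi2(h, 2) == pytest.approx(np.exp(-h / 2), abs=1e-12)


class TestTwoAndKSample:
    def test_identical_groups_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = st.one_way_anova([g, g, g])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_group_anova_equals_t_squared(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.4, 1.3, rng.integers(3, 12))
            t = st.t_test(x, y)
            f = st.one_way_anova([x, y])
            assert f.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)
            assert f.p == pytest.approx(t.p, abs=1e-10)

    def test_group_of_one_rejected(self):
        with pytest.raises(st.StatError):
            st.t_test([1.0], [1.0, 2.0])

    def test_tukey_identical_groups_all_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        ph = st.tukey_hsd([g, g, g])
        assert all(p == pytest.approx(1.0, abs=1e-9) for _, p in ph)

    def test_tukey_outlier_group_has_smallest_p(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.2, 1, 8)
        c = rng.normal(8, 1, 8)
        ph = dict(st.tukey_hsd([a, b, c], names=["a", "b", "c"]))
        assert max(ph[("a", "c")], ph[("b", "c")]) < ph[("a", "b")]

    def test_tukey_matches_scipy_reference(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in [(0, 6), (1, 9), (0.5, 7)]]
        ours = dict(st.tukey_hsd(groups))
        ref = sps.tukey_hsd(*groups)
        for (i, j) in itertools.combinations(range(3), 2):
            assert ours[(f"g{i}", f"g{j}")] == pytest.approx(
                float(ref.pvalue[i, j]), abs=1e-12)


def _enumerated_two_sided_p(x, y):
    """Independent brute-force null of the first-sample rank sum."""
    pooled = np.concatenate([x, y])
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    w_obs = ranks[: len(x)].sum()
    n = len(pooled)
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), len(x))]
    sums = np.array(sums)
    lower = np.mean(sums <= w_obs)
    upper = np.mean(sums >= w_obs)
    return min(1.0, 2 * min(lower, upper))


class TestRankTests:
    def test_mw_complete_separation_4v4(self):
        res = st.mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.p == pytest.approx(2 / 70)
        assert res.statistic == pytest.approx(1 + 2 + 3 + 4)

    def test_mw_exact_agrees_with_enumeration_sweep(self, rng):
        for n1 in range(1, 7):
            for n2 in range(max(n1, 2), 7):
                x = rng.normal(0, 1, n1)
                y = rng.normal(0.5, 1, n2)
                res = st.mann_whitney(x, y)
                assert "exact" in res.decision_path[0]
                assert res.p == pytest.approx(_enumerated_two_sided_p(x, y))

    def test_mw_interleaved_p_near_one(self):
        res = st.mann_whitney([1, 3, 5, 7], [2, 4, 6, 8])
        assert res.p > 0.65

    def test_mw_normal_approx_matches_scipy(self, rng):
        x = rng.normal(0, 1, 18)
        y = rng.normal(0.7, 1, 16)
        res = st.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_kruskal_matches_scipy_with_ties(self, rng):
        groups = [np.round(rng.normal(m, 1, 7), 1) for m in (0, 0.5, 1.0)]
        res = st.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-12)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_kruskal_identical_groups(self):
        res = st.kruskal_wallis([[1.0, 2.0]] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)


class TestAndersonDarling:
    def test_constant_sample_errors(self):
        with pytest.raises(st.StatError):
            st.anderson_darling([2.0] * 10)

    def test_null_rejection_rate_near_alpha(self, rng):
        rej = sum(st.anderson_darling(rng.normal(0, 1, 30)).p < 0.05
                  for _ in range(2000))
        assert 0.03 <= rej / 2000 <= 0.07

    def test_contaminated_samples_detected(self, rng):
        rej = 0
        for _ in range(200):
            x = rng.normal(0, 1, 50)
            bad = rng.random(50) < 0.2
            x[bad] = rng.normal(0, 6, bad.sum())
            rej += st.anderson_darling(x).p < 0.05
        assert rej / 200 > 0.5


class TestPermutationAnova:
    def test_requires_seed_and_min_b(self):
        g = [[1.0, 2.0], [3.0, 4.0]]
        with pytest.raises(st.StatError):
            st.permutation_anova(g, B=999, seed=None)
        with pytest.raises(st.StatError):
            st.permutation_anova(g, B=50, seed=1)

    def test_huge_separation_hits_lower_bound(self, rng):
        # groups big enough that a shuffle reproducing the split is
        # essentially impossible (2/C(20,10) per draw)
        g = [rng.normal(0, 0.1, 10), rng.normal(100, 0.1, 10)]
        res = st.permutation_anova(g, B=199, seed=3)
        assert res.p == pytest.approx(1 / 200)

    def test_converges_to_parametric_on_large_normal_samples(self, rng):
        g = [rng.normal(0, 1, 60), rng.normal(0.5, 1, 60), rng.normal(0.2, 1, 60)]
        pa = st.one_way_anova(g).p
        pp = st.permutation_anova(g, B=9999, seed=5).p
        mc_sd = np.sqrt(pa * (1 - pa) / 9999)
        assert abs(pp - pa) <= 2 * mc_sd + 1e-4

    def test_reproducible_for_fixed_seed(self, rng):
        g = [rng.normal(0, 1, 8) for _ in range(3)]
        p1 = st.permutation_anova(g, B=499, seed=7).p
        p2 = st.permutation_anova(g, B=499, seed=7).p
        assert p1 == p2


class TestDecisionPipeline:
    def test_two_groups_never_tukey(self, rng):
        res = st.decision_pipeline([rng.normal(0, 1, 6), rng.normal(5, 1, 6)],
                                   st.DecisionConfig(seed=1))
        assert res.statistic_kind == "t"
        assert res.posthoc == []

    def test_stars_scheme(self):
        assert st.stars_for(0.04) == "*"
        assert st.stars_for(0.004) == "**"       # between 0.005 and 0.001
        assert st.stars_for(0.0004) == "***"
        assert st.stars_for(0.2) == "ns"

    def test_significant_nonnormal_path_order(self, rng):
        # lognormal groups with a real shift: significant and non-normal
        g = [np.exp(rng.normal(0, 1, 15)),
             np.exp(rng.normal(2, 1, 15)),
             np.exp(rng.normal(0, 1, 15))]
        res = st.decision_pipeline(g, st.DecisionConfig(seed=2, permutation_B=199))
        path = res.decision_path
        ia = path.index("anova")
        ig = path.index("anderson_darling_gate")
        ip = next(i for i, s in enumerate(path) if s.startswith("permutation"))
        assert ia < ig < ip
        assert "anderson_darling" in res.extra
        assert "permutation_anova" in res.extra

    def test_nonparametric_routing(self, rng):
        g2 = st.decision_pipeline([rng.normal(0, 1, 5), rng.normal(1, 1, 5)],
                                  nonparametric=True)
        assert g2.statistic_kind == "W_ranksum"
        g3 = st.decision_pipeline([rng.normal(m, 1, 5) for m in (0, 1, 2)],
                                  nonparametric=True)
        assert g3.statistic_kind == "H"
        assert len(g3.posthoc) == 3

    def test_insignificant_anova_skips_gate(self, rng):
        g = [rng.normal(0, 1, 5) for _ in range(3)]
        # under the null this is almost always insignificant; force it
        g = [np.array([1.0, 2.0, 3.0])] * 3
        res = st.decision_pipeline(g, st.DecisionConfig(seed=1))
        assert "anderson_darling_gate" not in res.decision_path
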