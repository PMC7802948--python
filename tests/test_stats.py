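import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diaus.stats import (
    bonferroni_pairwise,
    fisher_f_agreement,
    one_way_anova,
    pearson_fit,
    unpaired_t,
)


class TestOneWayAnova:
    def test_two_groups_equals_t_squared(self, rng):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0.5, 1, size=9)
        res = one_way_anova([a, b])
        t, p_t = unpaired_t(a, b)
        assert res.F == pytest.approx(t**2, abs=1e-10)
        assert res.p_anova == pytest.approx(p_t, abs=1e-10)

    def test_identical_groups_degenerate(self):
        g = [1.0, 1.0, 1.0]
        res = one_way_anova([g, g, g])
        assert res.F == 0.0
        assert res.p_anova == 1.0

    def test_dof_bookkeeping(self, rng):
        groups = [rng.normal(size=n) for n in (5, 7, 9, 4)]
        res = one_way_anova(groups)
        assert res.df_between == 3
        assert res.df_within == 25 - 4

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import f_oneway
        groups = [rng.normal(size=8) for _ in range(4)]
        res = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_anova == pytest.approx(ref.pvalue, rel=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestBonferroni:
    def test_single_comparison_unadjusted(self, rng):
        res = bonferroni_pairwise([rng.normal(size=6), rng.normal(size=6)])
        (c,) = res.pairwise
        assert c.p_adjusted == pytest.approx(c.p_raw)

    def test_adjustment_multiplies_and_caps(self, rng):
        groups = [rng.normal(loc=m, size=6) for m in (0, 0.1, 0.2, 5.0)]
        res = bonferroni_pairwise(groups)
        m = len(res.pairwise)
        assert m == 6
        for c in res.pairwise:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * m))
            assert 0 <= c.p_adjusted <= 1

    def test_per_pair_variance_matches_plain_t(self, rng):
        a, b, c = (rng.normal(size=7) for _ in range(3))
        res = bonferroni_pairwise([a, b, c], variance="per_pair")
        for comp, (x, y) in zip(res.pairwise, [(a, b), (a, c), (b, c)]):
            t, p = unpaired_t(x, y)
            assert comp.t == pytest.approx(t)
            assert comp.p_raw == pytest.approx(p)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_adjusted_p_monotone_in_raw_p(self, p1, p2):
        m = 6
        a1, a2 = min(1, p1 * m), min(1, p2 * m)
        assert (p1 <= p2) == (a1 <= a2) or a1 == a2


class TestUnpairedT:
    def test_identical_samples_give_zero_t(self):
        t, p = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_value(self):
        t, p = unpaired_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_welch_flag_changes_df_handling(self, rng):
        a = rng.normal(0, 1, size=6)
        b = rng.normal(0, 4, size=20)
        t_pooled, p_pooled = unpaired_t(a, b)
        t_welch, p_welch = unpaired_t(a, b, welch=True)
        assert p_pooled != p_welch


class TestFisherAgreement:
    def test_identical_vectors_agree(self):
        v = [1.0, 2.0, 3.0, 4.0]
        res = fisher_f_agreement(v, v)
        assert res.F == 1.0
        assert res.agreement

    def test_variance_ratio_four_matches_tables(self, rng):
        # construct samples with exact variance ratio 4 at n=10 vs n=10
        base = rng.normal(size=10)
        base = (base - base.mean()) / base.std(ddof=1)
        a = base * 2.0  # variance 4
        b = base * 1.0  # variance 1
        res = fisher_f_agreement(a, b)
        assert res.F == pytest.approx(4.0)
        # two-sided p for F(9,9) at 4.0, from distribution tables
        assert res.p_f == pytest.approx(0.0510, abs=2e-4)

    def test_same_distribution_operators_usually_agree(self, rng):
        agree = 0
        for _ in range(100):
            a = rng.normal(10, 2, size=12)
            b = rng.normal(10, 2, size=12)
            agree += fisher_f_agreement(a, b).agreement
        assert agree >= 90

    def test_f_is_larger_over_smaller(self, rng):
        a = rng.normal(0, 5, size=8)
        b = rng.normal(0, 0.5, size=8)
        res = fisher_f_agreement(a, b)
        assert res.F >= 1.0
        assert res.F == pytest.approx(
            max(a.var(ddof=1), b.var(ddof=1)) / min(a.var(ddof=1), b.var(ddof=1))
        )


class TestPearsonFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = pearson_fit(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        res = pearson_fit(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res.r == pytest.approx(num / den, abs=1e-12)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    def test_shuffled_y_loses_correlation(self, rng):
        x = np.arange(300.0)
        y = x + rng.normal(scale=5, size=300)
        strong = pearson_fit(x, y).r
        weak = pearson_fit(x, rng.permutation(y)).r
        assert strong > 0.99
        assert abs(weak) < 0.15

    def test_affine_invariance_sign_aware(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = pearson_fit(x, y).r
        assert pearson_fit(3 * x + 5, 2 * y - 1).r == pytest.approx(r0)
        assert pearson_fit(-3 * x + 5, y).r == pytest.approx(-r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
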