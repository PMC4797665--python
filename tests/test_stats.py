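import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from usagevis.dataio import UsageDataError
from usagevis.stats import (
    GroupSummary,
    analytic_two_sample_power,
    chi_square,
    moderator_report,
    pooled_t_from_samples,
    pooled_t_from_summary,
    welch_t,
    welch_t_from_samples,
)

summaries = st.builds(
    GroupSummary,
    n=st.integers(min_value=2, max_value=200),
    mean=st.floats(min_value=-50, max_value=50, allow_nan=False),
    sd=st.floats(min_value=0.1, max_value=20, allow_nan=False),
)


class TestPooledT:
    @pytest.mark.parametrize(
        "a,b,t_expected",
        [
            # weight loss by steps-diary reuse (non-reusers first)
            ((119, 2.63, 5.56), (17, 5.78, 6.87), -2.12),
            # age by steps-diary reuse
            ((119, 50.52, 12.45), (17, 58.82, 14.44), -2.52),
            # weight loss by food-diary reuse
            ((60, 3.11, 6.17), (76, 2.95, 5.53), 0.16),
        ],
    )
    def test_published_group_summaries_reproduce_t(self, a, b, t_expected):
        res = pooled_t_from_summary(GroupSummary(*a), GroupSummary(*b))
        assert res.statistic == pytest.approx(t_expected, abs=0.01)
        assert res.df == a[0] + b[0] - 2 == 134

    def test_identical_groups_give_zero_t_unit_p(self):
        g = GroupSummary(10, 5.0, 2.0)
        res = pooled_t_from_summary(g, g)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_degenerate_zero_variance(self):
        same = pooled_t_from_summary(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 1.0, 0.0))
        assert (same.statistic, same.p) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="infinite"):
            res = pooled_t_from_summary(
                GroupSummary(5, 2.0, 0.0), GroupSummary(5, 1.0, 0.0)
            )
        assert math.isinf(res.statistic) and res.p == 0.0

    def test_sample_route_matches_summary_route(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        a = pooled_t_from_samples(x, y)
        b = pooled_t_from_summary(GroupSummary.from_sample(x), GroupSummary.from_sample(y))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 15), rng.normal(1, 1.5, 20)
        res = pooled_t_from_samples(x, y)
        ref = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_from_samples([1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pooled_t_from_summary(GroupSummary(1, 0, 0), GroupSummary(3, 0, 1))

    @given(a=summaries, b=summaries)
    @settings(max_examples=150, deadline=None)
    def test_sign_antisymmetry(self, a, b):
        r1, r2 = pooled_t_from_summary(a, b), pooled_t_from_summary(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-9, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-9, abs=1e-12)

    def test_agrees_with_exhaustive_permutation_test(self):
        """On small samples the pooled-t p-value tracks the exact permutation
        p-value of the mean difference."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1, 4)
            res = pooled_t_from_samples(x, y)
            pooled = np.concatenate([x, y])
            obs = abs(x.mean() - y.mean())
            count = 0
            combos = list(itertools.combinations(range(8), 4))
            for idx in combos:
                mask = np.zeros(8, bool)
                mask[list(idx)] = True
                if abs(pooled[mask].mean() - pooled[~mask].mean()) >= obs - 1e-12:
                    count += 1
            p_perm = count / len(combos)
            assert res.p == pytest.approx(p_perm, abs=0.12)


class TestWelch:
    def test_frozen_textbook_oracle(self):
        # hand-computed: t = -1/sqrt(0.1+0.4), df = 0.25/((0.01+0.16)/9)
        res = welch_t(GroupSummary(10, 0, 1), GroupSummary(10, 1, 2))
        assert res.statistic == pytest.approx(-1.414214, abs=1e-6)
        assert res.df == pytest.approx(13.235294, abs=1e-6)
        assert res.p == pytest.approx(0.18039013, abs=1e-6)

    def test_equal_variance_equal_n_matches_pooled_exactly(self):
        a, b = GroupSummary(12, 1.0, 2.5), GroupSummary(12, 3.0, 2.5)
        w, p = welch_t(a, b), pooled_t_from_summary(a, b)
        assert w.statistic == pytest.approx(p.statistic, rel=1e-12)
        assert w.df == pytest.approx(p.df, rel=1e-12)

    def test_identical_groups(self):
        g = GroupSummary(8, 2.0, 1.0)
        assert welch_t(g, g).statistic == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 3, 25)
        res = welch_t_from_samples(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    @given(a=summaries, b=summaries)
    @settings(max_examples=150, deadline=None)
    def test_df_never_exceeds_pooled_df(self, a, b):
        assert welch_t(a, b).df <= a.n + b.n - 2 + 1e-9


class TestChiSquare:
    def test_zero_under_exact_independence(self):
        rows, cols = np.array([10, 30]), np.array([2, 3, 5])
        table = np.outer(rows, cols)
        assert chi_square(table).statistic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "table,stat,df",
        [
            ([[10, 20], [30, 40]], 0.7936508, 1),  # N(ad-bc)^2 / product of margins
            ([[5, 0], [0, 5]], 10.0, 1),
        ],
    )
    def test_two_by_two_closed_form(self, table, stat, df):
        res = chi_square(table)
        assert res.statistic == pytest.approx(stat, abs=1e-6)
        assert res.df == df

    def test_invariant_under_permutation(self):
        t = np.array([[5, 9, 2], [7, 1, 6]])
        base = chi_square(t).statistic
        assert chi_square(t[::-1]).statistic == pytest.approx(base)
        assert chi_square(t[:, [2, 0, 1]]).statistic == pytest.approx(base)

    def test_scales_linearly_with_counts(self):
        t = np.array([[10, 20], [30, 40]])
        assert chi_square(3 * t).statistic == pytest.approx(3 * chi_square(t).statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(UsageDataError):
            chi_square([[0, 0], [3, 4]])

    def test_too_small_or_negative_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[1, 2]])
        with pytest.raises(ValueError):
            chi_square([[1, -2], [3, 4]])


class TestModeratorReport:
    @pytest.fixture
    def users(self):
        rng = np.random.default_rng(3)
        n = 60
        ind = (rng.random(n) < 0.3).astype(int)
        return pd.DataFrame(
            {
                "used": ind,
                "age": rng.normal(50, 10, n),
                "arm": rng.choice(["a", "b", "c"], n),
                "weight_change_kg": 2.0 + 3.0 * ind + rng.normal(0, 2, n),
            },
            index=[f"u{i}" for i in range(n)],
        )

    def test_routes_numeric_to_t_and_categorical_to_chi2(self, users):
        rep = moderator_report(users, "used", ["age", "arm"], outcome="weight_change_kg")
        assert list(rep["variable"]) == ["age", "arm", "weight_change_kg"]
        assert list(rep["test"]) == ["pooled t", "chi-square", "pooled t"]
        assert rep["p"].between(0, 1).all()

    def test_sign_convention_nonusers_minus_users(self, users):
        rep = moderator_report(users, "used", ["weight_change_kg"])
        # users gain +3 on the outcome, so (group0 - group1) is negative
        assert rep.loc[0, "statistic"] < 0
        assert rep.loc[0, "mean1"] > rep.loc[0, "mean0"]

    def test_welch_flag_and_bh_column(self, users):
        rep = moderator_report(users, "used", ["age"], welch=True, adjust=True)
        assert rep.loc[0, "test"] == "welch t"
        assert "p_bh" in rep.columns
        assert rep.loc[0, "p_bh"] >= rep.loc[0, "p"] - 1e-12

    def test_empty_variable_list(self, users):
        assert len(moderator_report(users, "used", [])) == 0

    def test_constant_indicator_rejected(self, users):
        users = users.assign(always=1)
        with pytest.raises(UsageDataError, match="constant"):
            moderator_report(users, "always", ["age"])

    def test_nonbinary_indicator_rejected(self, users):
        users = users.assign(tri=np.arange(len(users)) % 3)
        with pytest.raises(UsageDataError, match="binary"):
            moderator_report(users, "tri", ["age"])

    def test_unknown_names_rejected(self, users):
        with pytest.raises(UsageDataError):
            moderator_report(users, "nope", ["age"])
        with pytest.raises(UsageDataError):
            moderator_report(users, "used", ["nope"])


class TestAnalyticPower:
    def test_alpha_recovered_under_null(self):
        assert analytic_two_sample_power(119, 17, 0.0, 5.73) == pytest.approx(0.05, abs=1e-9)

    def test_moderate_effect_power_between_half_and_two_thirds(self):
        # ncp ~ 2.12 at the steps-diary configuration
        p = analytic_two_sample_power(119, 17, 3.15, 5.73)
        assert 0.5 < p < 0.65
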