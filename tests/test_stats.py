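"""Cohort statistics: comparisons, correlation, logistic model, OR arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octaquant import (StatsError, compare_groups, holm_adjust, logistic_fit,
                       or_derivations, recurrence_percentage,
                       snellen_to_logmar, spearman_corr)


class TestSnellen:
    @pytest.mark.parametrize("acuity,expected", [
        ("20/20", 0.0),
        ("20/200", 1.0),
        ("20/32", -math.log10(20 / 32)),
        ((20, 40), -math.log10(0.5)),
        (1.0, 0.0),
    ])
    def test_conversion(self, acuity, expected):
        assert snellen_to_logmar(acuity) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            snellen_to_logmar((0, 20))


def _two_group_table(a, b):
    return pd.DataFrame({
        "value": list(a) + list(b),
        "grp": [0] * len(a) + [1] * len(b)})


class TestCompareGroups:
    def test_identical_samples_null(self):
        a = [1.0, 2.0, 5.0, 9.0, 12.0]
        res = compare_groups(_two_group_table(a, a), "value", "grp",
                             "mann_whitney")
        assert res.p_value > 0.9

    def test_mann_whitney_exact_matches_enumeration(self):
        """{1,2,3} vs {4,5,6}: enumerate all 20 rank assignments by hand."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(_two_group_table(a, b), "value", "grp",
                             "mann_whitney")
        # oracle: distribution of U over all C(6,3) assignments
        ranks = range(1, 7)
        u_obs = sum(1 for x in a for y in b if x > y)  # = 0
        u_vals = []
        for combo in itertools.combinations(ranks, 3):
            r1 = sum(combo)
            u_vals.append(r1 - 3 * 4 / 2)
        u_vals = np.array(u_vals)
        p_exact = np.mean(np.minimum(u_vals, 9 - u_vals)
                          <= min(u_obs, 9 - u_obs))
        assert res.p_value == pytest.approx(p_exact) == pytest.approx(0.1)
        assert "exact" in res.test

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        """[[3,0],[0,3]]: two-sided Fisher p = 0.1 by direct enumeration."""
        table = pd.DataFrame({
            "grp": [0, 0, 0, 1, 1, 1],
            "cat": ["x", "x", "x", "y", "y", "y"]})
        res = compare_groups(table, "cat", "grp", "fisher")
        # oracle: hypergeometric over all 2x2 tables with the same margins
        probs = []
        for k in range(0, 4):  # top-left cell
            probs.append(math.comb(3, k) * math.comb(3, 3 - k) / math.comb(6, 3))
        p_obs = probs[3]
        p_two_sided = sum(p for p in probs if p <= p_obs + 1e-12)
        assert res.p_value == pytest.approx(p_two_sided) == pytest.approx(0.1)

    def test_chi2_warns_on_small_expected_counts(self):
        table = pd.DataFrame({"grp": [0, 0, 0, 1, 1, 1],
                              "cat": ["x", "x", "y", "y", "y", "x"]})
        with pytest.warns(UserWarning, match="expected count"):
            res = compare_groups(table, "cat", "grp", "chi2")
        assert res.note

    def test_wilcoxon_paired(self):
        a = np.arange(1.0, 13.0)
        b = a + 1.5
        res = compare_groups(_two_group_table(a, b), "value", "grp",
                             "wilcoxon_paired")
        assert res.p_value < 0.01

    def test_empty_group_rejected(self):
        table = pd.DataFrame({"value": [1.0, 2.0], "grp": [0, 0]})
        with pytest.raises(StatsError):
            compare_groups(table, "value", "grp")


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x ** 3).rho == pytest.approx(1.0)
        assert spearman_corr(x, -x).rho == pytest.approx(-1.0)

    def test_tie_handling_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0, 10.0, 9.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y).rho == pytest.approx(oracle)

    def test_constant_vector_flagged(self):
        res = spearman_corr(np.ones(6), np.arange(6.0))
        assert res.undefined and math.isnan(res.rho)


def _logistic_table(n, beta0, beta, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(beta0 + beta * x)))
    return pd.DataFrame({"x": x, "y": (rng.random(n) < p).astype(int)})


class TestLogisticFit:
    def test_constant_outcome_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1, 1, 1]})
        with pytest.raises(StatsError):
            logistic_fit(table, "y", ["x"])

    def test_collinear_terms_rejected(self):
        table = _logistic_table(200, 0.0, 1.0, 0)
        table["x2"] = 2 * table["x"]
        with pytest.raises(StatsError, match="collinear"):
            logistic_fit(table, "y", ["x", "x2"])

    def test_ci_brackets_or_and_or_is_exp_coef(self):
        table = _logistic_table(500, -0.5, 0.8, 1)
        fit = logistic_fit(table, "y", ["x"])
        t = fit.term("x")
        assert t.ci_low < t.odds_ratio < t.ci_high
        assert t.odds_ratio == pytest.approx(math.exp(t.coefficient))
        assert fit.converged

    def test_univariate_mode_fits_each_term_alone(self):
        table = _logistic_table(300, 0.0, 0.7, 2)
        table["z"] = np.random.default_rng(3).normal(0, 1, 300)
        fits = logistic_fit(table, "y", ["x", "z"], mode="univariate")
        assert set(fits) == {"x", "z"}
        assert fits["x"].terms[0].p_value < 0.05 < fits["z"].terms[0].p_value

    def test_recovers_true_coefficient_within_3se(self):
        table = _logistic_table(2000, -0.3, 0.6, 4)
        t = logistic_fit(table, "y", ["x"]).term("x")
        assert abs(t.coefficient - 0.6) < 3 * t.se


class TestOrDerivations:
    @pytest.mark.parametrize("or_,pct,k", [
        (1.044, 4.4, 17),
        (2.0, 100.0, 1),
        (1.5, 50.0, 2),   # 1.5^1 < 2 <= 1.5^2
    ])
    def test_printed_arithmetic(self, or_, pct, k):
        d = or_derivations(or_)
        assert d.pct_increase_per_unit == pytest.approx(pct)
        assert d.doubling_units == k

    def test_or_at_most_one_rejected(self):
        with pytest.raises(StatsError):
            or_derivations(1.0)

    @given(st.floats(min_value=1.001, max_value=10.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_doubling_units_monotone_in_or(self, or_lo, bump):
        or_hi = or_lo * (1.0 + bump)
        assert or_derivations(or_hi).doubling_units \
            <= or_derivations(or_lo).doubling_units

    @given(st.floats(min_value=1.01, max_value=5.0))
    def test_doubling_definition(self, or_):
        k = or_derivations(or_).doubling_units
        assert or_ ** k >= 2.0
        if k > 1:
            assert or_ ** (k - 1) < 2.0


def test_recurrence_percentage():
    table = pd.DataFrame({"recurrent": [True] * 22 + [False] * 54})
    assert recurrence_percentage(table) == pytest.approx(100 * 22 / 76)


def test_holm_adjustment_orders_and_caps():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert adj[0] == pytest.approx(0.04)
    assert (adj <= 1.0).all() and (adj >= np.asarray(p)).all()
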