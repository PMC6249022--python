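"""Logistic association fits, eligibility rules and the secondary tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sigassoc as sa


def binary_design(n11, n01, n10, n00):
    """y/x vectors for a 2x2 table: x=1 (n11 mutant, n01 wild-type),
    x=0 (n10 mutant, n00 wild-type)."""
    y = np.r_[np.ones(n11), np.zeros(n01), np.ones(n10), np.zeros(n00)]
    x = np.r_[np.ones(n11 + n01), np.zeros(n10 + n00)]
    return y, x


class TestLogisticFit:
    def test_binary_covariate_matches_cross_product_ratio(self):
        y, x = binary_design(8, 12, 5, 45)
        fit = sa.fit_logistic(y, x)
        assert fit.odds_ratio == pytest.approx(6.0, rel=1e-6)
        assert fit.fit_status == "ok"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(1, 30), st.integers(1, 30),
            st.integers(1, 30), st.integers(1, 30),
        )
    )
    def test_cross_product_oracle_property(self, cells):
        """On any all-cells-positive 2x2 table the logistic MLE odds ratio
        equals the closed-form cross-product ratio."""
        n11, n01, n10, n00 = cells
        y, x = binary_design(n11, n01, n10, n00)
        fit = sa.fit_logistic(y, x)
        oracle = (n11 * n00) / (n01 * n10)
        assert fit.odds_ratio == pytest.approx(oracle, rel=1e-6)

    def test_agrees_with_statsmodels_on_continuous_covariate(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        x = rng.beta(0.5, 2.0, size=400)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1.2 + 1.6 * x))))
        fit = sa.fit_logistic(y, x)
        sm_fit = statsmodels.Logit(y, statsmodels.add_constant(x)).fit(disp=0)
        assert fit.beta0 == pytest.approx(sm_fit.params[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(sm_fit.params[1], abs=1e-6)
        assert fit.se_beta1 == pytest.approx(sm_fit.bse[1], rel=1e-5)
        assert fit.p_value == pytest.approx(sm_fit.pvalues[1], rel=1e-5)

    def test_antisymmetry_under_covariate_negation(self):
        rng = np.random.default_rng(6)
        x = rng.random(200)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 2 * x))))
        f_pos = sa.fit_logistic(y, x)
        f_neg = sa.fit_logistic(y, -x)
        assert f_neg.beta1 == pytest.approx(-f_pos.beta1, abs=1e-8)
        assert f_neg.odds_ratio == pytest.approx(1 / f_pos.odds_ratio, rel=1e-8)

    def test_constant_covariate_flagged_with_p_one(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        fit = sa.fit_logistic(y, np.full(10, 0.3))
        assert fit.fit_status == "no_convergence"
        assert fit.p_value == 1.0

    def test_single_class_response_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            sa.fit_logistic(np.ones(10), np.arange(10.0))

    def test_perfect_separation_is_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = sa.fit_logistic(y, x)
        assert fit.fit_status == "separation"

    def test_batch_equals_sequential_fits(self):
        rng = np.random.default_rng(7)
        x = rng.random(150)
        Y = rng.binomial(1, 0.3, size=(150, 6))
        Y[:, 0] = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 2 * x))))
        b0, b1, se, p, status = sa.fit_logistic_batch(Y, x)
        for j in range(6):
            single = sa.fit_logistic(Y[:, j], x)
            assert b1[j] == pytest.approx(single.beta1, abs=1e-9)
            assert p[j] == pytest.approx(single.p_value, rel=1e-9)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "beta1, expected", [(0.0, 1.0), (math.log(2), 2.0), (1.0, math.e)]
    )
    def test_closed_form(self, beta1, expected):
        assert sa.odds_ratio(beta1) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sa.odds_ratio(float("inf"))


class TestEligiblePairs:
    @staticmethod
    def cohort(n, n_mutant, exposures_col):
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        calls = pd.DataFrame({"drv": [1] * n_mutant + [0] * (n - n_mutant)}, index=idx)
        expo = pd.DataFrame({"sig": exposures_col}, index=idx)
        ctypes = pd.Series("T", index=idx)
        return calls, expo, ctypes

    def test_nine_mutants_excluded_ten_included(self):
        for n_mut, expected in [(9, 0), (10, 1)]:
            calls, expo, ctypes = self.cohort(40, n_mut, [0.5] * 40)
            assert len(sa.eligible_pairs(calls, expo, ctypes)) == expected

    def test_exposure_boundary_is_inclusive(self):
        column = [0.20] * 10 + [0.0] * 30
        calls, expo, ctypes = self.cohort(40, 12, column)
        assert len(sa.eligible_pairs(calls, expo, ctypes)) == 1
        column = [0.1999] * 10 + [0.0] * 30
        calls, expo, ctypes = self.cohort(40, 12, column)
        assert len(sa.eligible_pairs(calls, expo, ctypes)) == 0

    def test_synthetic_cohort_matches_direct_recount(self, mixed_cohort):
        _, catalogs, calls, _, exposures = mixed_cohort
        triples = sa.eligible_pairs(calls, exposures, catalogs.cancer_types)
        for _, row in triples.sample(10, random_state=0).iterrows():
            idx = catalogs.cancer_types[
                catalogs.cancer_types == row["cancer_type"]
            ].index
            assert calls.loc[idx, row["driver"]].sum() == row["n_mutant"]
            assert (exposures.loc[idx, row["signature"]] >= 0.20).sum() == row[
                "n_sig_eligible"
            ]
            assert row["n_mutant"] >= 10 and row["n_sig_eligible"] >= 10


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = sa.mann_whitney_u([1, 2], [3, 4], sided="two")
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_show_no_evidence(self):
        _, p = sa.mann_whitney_u([1, 2, 3], [1, 2, 3], sided="two")
        assert p >= 0.99

    def test_separated_groups_one_sided(self):
        a = [10, 11, 12, 13, 14]
        b = [1, 2, 3, 4, 5]
        _, p = sa.mann_whitney_u(a, b, sided="one_greater")
        assert p < 0.05
        _, p_wrong_side = sa.mann_whitney_u(a, b, sided="one_less")
        assert p_wrong_side > 0.95

    def test_large_sample_matches_scipy_asymptotics(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.3, 1, 40)
        b = rng.normal(0.0, 1, 50)
        u, p = sa.mann_whitney_u(a, b, sided="two")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sa.mann_whitney_u([], [1.0])


class TestTTest:
    def test_identical_groups(self):
        t, p = sa.t_test_unpaired([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_is_degenerate(self):
        t, p = sa.t_test_unpaired([0, 0, 0, 0], [1, 1, 1, 1])
        assert p == 0.0

    def test_matches_direct_formula_and_scipy(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, p = sa.t_test_unpaired(a, b)
        # pooled variance 1, se = sqrt(2/3): t = -1 / sqrt(2/3)
        assert t == pytest.approx(-1 / math.sqrt(2 / 3))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            sa.t_test_unpaired([1.0], [1.0, 2.0])
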