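"""Percent change, Wilcoxon signed-rank, OLS, and the cohort change table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cvmorph.cohort import simulate_cohort_summary
from cvmorph.stats import (benjamini_hochberg, build_change_table, ols_regression,
                           paired_wilcoxon, percent_change, percent_change_magnitude,
                           percent_increase, wilcoxon_exact_bruteforce,
                           LongitudinalPair)


class TestPercentChange:
    def test_printed_worked_examples(self):
        assert round(percent_change_magnitude(186.5, 121.3), 1) == 35.0
        assert round(percent_change_magnitude(156.1, 116.4), 1) == 25.4
        assert round(percent_change_magnitude(75.7, 64.2), 1) == 15.2

    def test_identity_and_sign_conventions(self):
        assert percent_change(5.0, 5.0) == 0.0
        # a decrease is positive under the (initial - followup)/initial form
        assert percent_change(10.0, 8.0) == pytest.approx(20.0)
        # an increase is positive under the signed-increase form
        assert percent_increase(10.0, 12.0) == pytest.approx(20.0)
        assert percent_change(10.0, 12.0) == pytest.approx(-20.0)

    def test_zero_initial_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6), st.floats(0.01, 1e3))
    def test_scale_invariance(self, a, b, k):
        assert percent_change(k * a, k * b) == pytest.approx(percent_change(a, b),
                                                             rel=1e-9)


class TestWilcoxon:
    def test_five_positive_pairs_exact_p(self):
        """All 5 differences positive: two-sided exact p = 2/32 = 0.0625."""
        r = paired_wilcoxon([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
        assert r.p_value == pytest.approx(0.0625)
        assert r.extra["method"] == "exact"

    def test_n8_matches_full_enumeration(self):
        d = np.array([1, 2, 3, 4, 5, 6, 7, -8.0])
        r = paired_wilcoxon(np.zeros(8), d)
        assert r.p_value == pytest.approx(wilcoxon_exact_bruteforce(d))

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError, match="all paired differences are zero"):
            paired_wilcoxon([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_single_nonzero_difference_is_small_sample(self):
        a = [1, 2, 3, 4, 5, 6.0]
        b = [1, 2, 3, 4, 5, 7.0]
        with pytest.raises(ValueError, match="need >= 5"):
            paired_wilcoxon(a, b)

    def test_missing_pairs_dropped(self):
        a = [1, 2, 3, 4, 5, np.nan]
        b = [2, 3, 4, 5, 6, 1.0]
        r = paired_wilcoxon(a, b)
        assert r.n == 5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_exact_p_matches_bruteforce_enumeration(self, seed):
        """Tie-aware exact null equals 2^n enumeration for n <= 10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = rng.integers(-5, 6, n).astype(float)
        d = d[d != 0]
        if len(d) < 5:
            return
        p = paired_wilcoxon(np.zeros(len(d)), d).p_value
        assert p == pytest.approx(wilcoxon_exact_bruteforce(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(0.4, 1.0, 15)
            p_ours = paired_wilcoxon(np.zeros(15), d).p_value
            p_scipy = sps.wilcoxon(d, mode="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.2, 1.0, 60)
        r = paired_wilcoxon(np.zeros(60), d)
        assert r.extra["method"] == "normal-approx"
        p_scipy = sps.wilcoxon(d, correction=True, mode="approx").pvalue
        assert r.p_value == pytest.approx(p_scipy, rel=0.01)


class TestOLS:
    def test_perfect_linear_fit_exact_coefficients(self):
        x = np.arange(10.0)
        res = ols_regression(2 * x + 1, pd.DataFrame({"x": x}))
        by_term = {r.term: r for r in res}
        assert by_term["x"].coefficient == pytest.approx(2.0, abs=1e-9)
        assert by_term["const"].coefficient == pytest.approx(1.0, abs=1e-9)
        assert by_term["x"].ci_high - by_term["x"].ci_low < 1e-9

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear.*x.*x2"):
            ols_regression(x, pd.DataFrame({"x": x, "x2": x}))

    def test_constant_column_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="constant covariate"):
            ols_regression(x, pd.DataFrame({"x": x, "c": np.ones(10)}))

    def test_ci_coverage_under_null(self):
        """Slope CI covers 0 in >= 90% of 100 pure-noise repeats."""
        rng = np.random.default_rng(7)
        covered = 0
        x = rng.normal(size=200)
        for _ in range(100):
            y = rng.normal(size=200)
            res = ols_regression(y, pd.DataFrame({"x": x}))
            term = next(r for r in res if r.term == "x")
            covered += term.ci_low <= 0 <= term.ci_high
        assert covered >= 90

    def test_noisy_recovery_small_bias(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        slopes = [next(r for r in ols_regression(3.0 * x + rng.normal(size=200),
                                                 pd.DataFrame({"x": x}))
                       if r.term == "x").coefficient for _ in range(50)]
        assert abs(np.mean(slopes) / 3.0 - 1) < 0.02

    def test_complete_case_reports_n(self):
        x = np.arange(20.0)
        y = 2 * x
        y[3] = np.nan
        res = ols_regression(y, pd.DataFrame({"x": x}))
        assert res[0].n == 19


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # matches statsmodels
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, expected)


class TestChangeTable:
    def test_injected_shift_recovered_in_summary_cohort(self):
        cohort = simulate_cohort_summary(n_subjects=30, diameter_change_pct=6.0,
                                         n_chunks=4, seed=0)
        tab = build_change_table(cohort)
        area = tab[tab.feature == "area_mm2"]
        diam = tab[tab.feature == "max_diameter_mm"]
        assert np.all(area.p_value < 0.05)
        assert np.allclose(diam.pct_increase, 6.0, atol=1.0)
        assert np.allclose(area.pct_increase, 12.36, atol=1.5)
        # the sign conventions mirror each other
        np.testing.assert_allclose(tab.pct_increase, -tab.pct_change_paper_sign)

    def test_null_cohort_type_I_error_near_nominal(self):
        """Fraction of p < 0.05 across cells and repeats ~ 0.05 +- 0.03."""
        hits, total = 0, 0
        for rep in range(20):
            cohort = simulate_cohort_summary(n_subjects=20, diameter_change_pct=0.0,
                                             n_chunks=3, seed=100 + rep)
            tab = build_change_table(cohort, features=["area_mm2", "max_diameter_mm",
                                                       "perimeter_mm"])
            hits += int((tab.p_value < 0.05).sum())
            total += len(tab)
        assert abs(hits / total - 0.05) < 0.03

    def test_single_subject_rejected(self):
        cohort = simulate_cohort_summary(n_subjects=1, seed=0)
        with pytest.raises(ValueError, match=">= 5 subjects"):
            build_change_table(cohort)

    def test_subject_missing_timepoint_excluded_with_warning(self, caplog):
        cohort = simulate_cohort_summary(n_subjects=6, seed=3)
        cohort[2] = LongitudinalPair(subject_id=cohort[2].subject_id,
                                     baseline=cohort[2].baseline, followup=None,
                                     covariates=cohort[2].covariates)
        import logging

        with caplog.at_level(logging.WARNING, logger="cvmorph.stats"):
            tab = build_change_table(cohort)
        assert tab.n.max() == 5
        assert any("missing a timepoint" in r.message for r in caplog.records)

    def test_covariate_betas_emitted_with_ci(self):
        cohort = simulate_cohort_summary(n_subjects=25, diameter_change_pct=2.0,
                                         n_chunks=2, seed=9)
        tab = build_change_table(cohort, features=["area_mm2"],
                                 covariate_names=["sbp", "age"])
        for cov in ("sbp", "age"):
            assert f"beta_{cov}" in tab.columns
            ok = tab[f"beta_{cov}"].notna()
            assert ok.all()
            assert np.all(tab.loc[ok, f"ci_low_{cov}"] <= tab.loc[ok, f"beta_{cov}"])
            assert np.all(tab.loc[ok, f"beta_{cov}"] <= tab.loc[ok, f"ci_high_{cov}"])
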