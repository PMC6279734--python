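"""t-tests against hand-computed pooled-variance oracles; calibration."""

import numpy as np
import pytest

from gatedpet.curves import CardiacFunctionResult
from gatedpet.errors import DataError
from gatedpet.stats import (compare_cohorts, summarize, ttest_independent,
                            ttest_independent_summary, ttest_paired)


def pooled_t_oracle(a, b):
    """Hand-rolled pooled-variance Student's t (the independent check)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def make_result(**kw):
    base = dict(edv=400.0, esv=160.0, stroke_volume=240.0, ef=60.0, pfr=12.0,
                third_mfr=10.0, tpfr=36.0, hr=330.0)
    base.update(kw)
    return CardiacFunctionResult(**base)


class TestIndependent:
    def test_identical_groups(self):
        r = ttest_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_computed_example(self):
        r = ttest_independent([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4
        assert r.p == pytest.approx(0.0213, abs=2e-4)

    def test_group_swap_negates_t(self):
        a, b = [1.0, 2.0, 4.0], [2.5, 3.5, 6.0]
        r1 = ttest_independent(a, b)
        r2 = ttest_independent(b, a)
        assert r2.t == pytest.approx(-r1.t)
        assert r2.p == pytest.approx(r1.p)

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(5.0, 2.0, size=rng.integers(3, 9))
            b = rng.normal(6.0, 1.0, size=rng.integers(3, 9))
            r = ttest_independent(a, b)
            assert r.t == pytest.approx(pooled_t_oracle(a, b), rel=1e-10)

    def test_zero_variance_paths(self):
        assert ttest_independent([2.0, 2.0], [2.0, 2.0]).p == 1.0
        with pytest.raises(DataError):
            ttest_independent([2.0, 2.0], [3.0, 3.0])


class TestSummaryForm:
    def test_equals_raw_data_form_exactly(self, rng):
        a = rng.normal(10.0, 2.0, 7)
        b = rng.normal(11.0, 2.5, 5)
        raw = ttest_independent(a, b)
        summ = ttest_independent_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        assert summ.t == pytest.approx(raw.t, rel=1e-12)
        assert summ.p == pytest.approx(raw.p, rel=1e-12)
        assert summ.df == raw.df

    def test_pfr_group_comparison(self):
        """PFR 12.1+-0.8 vs 10.2+-1.0 at n = 6 each: p ~ 0.0046 (< 0.01)."""
        r = ttest_independent_summary(12.1, 0.8, 6, 10.2, 1.0, 6)
        assert r.t == pytest.approx(3.63, abs=0.01)
        assert r.df == 10
        assert r.p == pytest.approx(0.0046, abs=3e-4)
        assert r.significant(0.01)

    def test_tpfr_group_comparison(self):
        """TPFR 35.4+-2.7 vs 40.0+-4.2 at n = 6: p ~ 0.048, short of 0.01."""
        r = ttest_independent_summary(35.4, 2.7, 6, 40.0, 4.2, 6)
        assert r.p == pytest.approx(0.048, abs=2e-3)
        assert r.significant(0.05) and not r.significant(0.01)

    def test_equal_means_zero_sd(self):
        assert ttest_independent_summary(5.0, 0.0, 6, 5.0, 0.0, 6).p == 1.0

    def test_welch_differs_under_unequal_variance(self):
        classic = ttest_independent_summary(10.0, 1.0, 6, 11.0, 5.0, 6)
        welch = ttest_independent_summary(10.0, 1.0, 6, 11.0, 5.0, 6,
                                          welch=True)
        assert welch.df < classic.df


class TestPaired:
    def test_no_change(self):
        a = [1.0, 2.0, 3.0]
        r = ttest_paired(a, a)
        assert r.t == 0.0 and r.p == 1.0 and r.df == 2

    def test_constant_shift_is_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DataError):
            ttest_paired(a, a + 0.5)

    def test_matches_one_sample_oracle(self, rng):
        a = rng.normal(5.0, 1.0, 8)
        b = a + rng.normal(0.3, 0.4, 8)
        r = ttest_paired(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.t == pytest.approx(t_oracle, rel=1e-10)
        assert r.df == 7

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            ttest_paired([1.0, 2.0], [1.0, 2.0, 3.0])


def test_power_of_the_filling_rate_comparison():
    """Analytic power from the configured effect sizes: with PFR
    12.1+-0.8 vs 10.2+-1.0 at n = 6 each, the pooled t-test flags the
    difference at alpha = 0.01 in the majority of repeated experiments
    (noncentral-t computation)."""
    from scipy.stats import nct, t as tdist

    sp = np.sqrt((0.8 ** 2 + 1.0 ** 2) / 2.0)
    ncp = (12.1 - 10.2) / (sp * np.sqrt(2.0 / 6.0))
    df = 10
    for alpha, lo in ((0.01, 0.5), (0.05, 0.8)):
        crit = tdist.ppf(1.0 - alpha / 2.0, df)
        power = 1.0 - nct.cdf(crit, df, ncp) + nct.cdf(-crit, df, ncp)
        assert power > lo


def test_type_one_error_calibration():
    """Null rejection rate at alpha = 0.05 over 2000 simulated pairs of
    n = 6 cohorts stays inside the binomial 99% band."""
    rng = np.random.default_rng(42)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        a = rng.normal(12.0, 1.0, 6)
        b = rng.normal(12.0, 1.0, 6)
        if ttest_independent(a, b).p < 0.05:
            rejections += 1
    rate = rejections / n_sim
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rate - 0.05) < half_width


class TestCompareCohorts:
    def test_identical_cohorts_not_significant(self):
        cohort = [make_result(ef=60.0 + i) for i in range(5)]
        report = compare_cohorts(cohort, list(cohort))
        assert not report["significant"].any()
        assert (report["p"] == 1.0).all()

    def test_single_subject_rejected(self):
        with pytest.raises(DataError):
            compare_cohorts([make_result()], [make_result(), make_result()])

    def test_separated_groups_flagged(self, rng):
        a = [make_result(pfr=12.0 + rng.normal(0, 0.3)) for _ in range(6)]
        b = [make_result(pfr=9.0 + rng.normal(0, 0.3)) for _ in range(6)]
        report = compare_cohorts(a, b, labels=("ZL", "ZDF"))
        row = report.set_index("parameter").loc["pfr"]
        assert row["significant"]
        assert row["mean_ZL"] > row["mean_ZDF"]

    def test_summarize(self):
        summary = summarize([make_result(ef=58.0), make_result(ef=62.0)], "ef")
        assert summary.mean == 60.0
        assert summary.sd == pytest.approx(np.std([58.0, 62.0], ddof=1))
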