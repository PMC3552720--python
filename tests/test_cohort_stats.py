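"""Welch/paired t-tests, Fisher's exact test, sample size, cohort tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cmrperf import (
    GroupSummary,
    InputError,
    InsufficientDataError,
    ParameterError,
    SampleSizeSpec,
    UndefinedStatisticError,
    fisher_exact_2x2,
    paired_t,
    sample_size_two_group,
    summarize_cohort,
    welch_t,
)
from cmrperf.cohort_stats import SUMMARY_METRICS, format_report


class TestWelchT:
    def test_identical_summaries(self):
        g = GroupSummary(10, 5.0, 1.0)
        res = welch_t(g, g)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_heart_rate_change_row(self):
        # closed-form evaluation from rounded group summaries; the published
        # raw-data p (0.03) differs and must not be asserted
        res = welch_t(GroupSummary(10, -48, 11), GroupSummary(10, -35, 12))
        assert res.statistic == pytest.approx(-2.525, abs=2e-3)
        assert res.df == pytest.approx(17.9, abs=0.05)
        assert res.p_value == pytest.approx(0.021, abs=1e-3)

    def test_sample_mode_matches_summary_mode(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 17)
        r1 = welch_t(a, b)
        r2 = welch_t(GroupSummary.from_sample(a), GroupSummary.from_sample(b))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 30)))
            b = rng.normal(0.3, 1.7, int(rng.integers(5, 30)))
            ours = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_antisymmetric_in_group_order(self):
        a, b = GroupSummary(8, 1.0, 0.5), GroupSummary(12, 2.0, 1.5)
        r_ab, r_ba = welch_t(a, b), welch_t(b, a)
        assert r_ab.statistic == pytest.approx(-r_ba.statistic)
        assert r_ab.p_value == pytest.approx(r_ba.p_value)

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            welch_t(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 1.0, 0.0))


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1,2,3): mean 2, sd 1 -> t = 2*sqrt(3), df 2
        res = paired_t([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=2e-4)

    def test_matches_textbook_paired_test(self, rng):
        x = rng.normal(10, 2, 15)
        y = rng.normal(9, 2, 15)
        ours = paired_t(x - y)
        ref = sps.ttest_rel(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_constant_differences_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            paired_t([2.0, 2.0, 2.0])

    def test_single_difference_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_t([1.0])


class TestFisherExact:
    def test_printed_race_row(self):
        # 7/10 vs 5/10: exact two-sided p = 120076/184756
        res = fisher_exact_2x2([[7, 3], [5, 5]])
        assert res.p_value == pytest.approx(120076 / 184756, rel=1e-12)
        assert round(res.p_value, 2) == 0.65

    def test_zero_margin_gives_unity(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]).p_value == 1.0
        assert fisher_exact_2x2([[4, 0], [6, 0]]).p_value == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        # brute-force oracle: enumerate every table with the observed
        # margins and sum the point probabilities <= the observed one
        for _ in range(50):
            tab = rng.integers(0, 16, size=(2, 2))
            if tab.sum() == 0:
                continue
            a, b, c, d = map(int, tab.ravel())
            n, r1, c1 = a + b + c + d, a + b, a + c
            probs = {}
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                probs[k] = (math.comb(r1, k) * math.comb(n - r1, c1 - k)
                            / math.comb(n, c1))
            expected = sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-12))
            assert fisher_exact_2x2(tab).p_value == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_two_sided(self, rng):
        for _ in range(30):
            tab = rng.integers(0, 12, size=(2, 2))
            if tab.sum() == 0:
                continue
            ours = fisher_exact_2x2(tab).p_value
            ref = sps.fisher_exact(tab, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_point_probabilities_sum_to_one(self):
        # with margins 10/10 and 12/8 the hypergeometric weights total C(20,12)
        n, r1, c1 = 20, 10, 12
        total = sum(math.comb(r1, k) * math.comb(n - r1, c1 - k)
                    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1))
        assert total == math.comb(n, c1) == 125970

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestSampleSize:
    SPEC = SampleSizeSpec(mean=1.78, sd=0.60, relative_difference=0.25)

    def test_published_design_total(self):
        res = sample_size_two_group(self.SPEC)
        assert res.per_group == 29
        assert res.total == 58

    def test_variance_scaling(self):
        # quadrupling sd^2 quadruples the unrounded per-group n
        z = sps.norm.ppf(0.975) + sps.norm.ppf(0.80)
        delta = 0.25 * 1.78
        raw = 2 * 0.60**2 * z**2 / delta**2
        raw4 = 2 * (2 * 0.60) ** 2 * z**2 / delta**2
        assert raw4 == pytest.approx(4 * raw, rel=1e-12)
        res4 = sample_size_two_group(SampleSizeSpec(1.78, 1.20, 0.25))
        assert res4.per_group == math.ceil(raw4 - 1e-12)

    def test_exact_mode_at_least_normal_approximation(self):
        approx = sample_size_two_group(self.SPEC)
        exact = sample_size_two_group(self.SPEC, exact=True)
        assert exact.total >= approx.total
        assert exact.method == "noncentral_t"

    @pytest.mark.parametrize(
        "change,direction",
        [(dict(sd=0.9), +1), (dict(power=0.9), +1),
         (dict(relative_difference=0.4), -1), (dict(alpha=0.10), -1)],
    )
    def test_monotonicity(self, change, direction):
        base = sample_size_two_group(self.SPEC).total
        kw = dict(mean=1.78, sd=0.60, relative_difference=0.25,
                  alpha=0.05, power=0.80)
        kw.update(change)
        other = sample_size_two_group(SampleSizeSpec(**kw)).total
        assert (other - base) * direction >= 0

    def test_zero_effect_rejected(self):
        with pytest.raises(ParameterError):
            SampleSizeSpec(mean=1.78, sd=0.6, relative_difference=0.0)


def make_cohort(rows):
    return pd.DataFrame(rows)


def subject_row(i, group, rest, stress, recov, delayed=False):
    return {
        "subject_id": f"S{i}", "group": group, "rest": rest, "stress": stress,
        "recovery": recov, "mpri_rest": stress / rest, "mpri_recov": stress / recov,
        "pct_reduction": 100 * (stress / rest - stress / recov) / (stress / rest),
        "recovery_to_rest": recov / rest, "delayed": delayed,
    }


class TestSummarizeCohort:
    def test_constant_cohort_table_values(self):
        # every subject has MPRi-rest 2.0 and MPRi-recov 1.5 -> mean 2.0 (0),
        # 1.5 (0), per-subject percent difference 25
        rows = [subject_row(i, "none", 8.0, 16.0, 16.0 / 1.5) for i in range(5)]
        rows += [subject_row(i + 5, "aminophylline", 8.0, 16.0, 16.0 / 1.5)
                 for i in range(5)]
        summary = summarize_cohort(make_cohort(rows))
        row = summary.table.set_index("group").loc["none"]
        assert row["mpri_rest_mean"] == pytest.approx(2.0)
        assert row["mpri_rest_sd"] == pytest.approx(0.0, abs=1e-12)
        assert row["mpri_recov_mean"] == pytest.approx(1.5)
        assert row["pct_reduction_mean"] == pytest.approx(25.0)

    def test_zero_variance_paired_tests_reported_na(self):
        rows = [subject_row(i, "none", 8.0, 16.0, 12.0) for i in range(4)]
        rows += [subject_row(i + 4, "aminophylline", 8.0, 16.0, 12.0)
                 for i in range(4)]
        summary = summarize_cohort(make_cohort(rows))
        for tests in summary.within_group.values():
            assert all(t is None for t in tests.values())
        assert "n/a" in format_report(summary)

    def test_schema_contains_all_metric_cells(self):
        rows = [subject_row(i, "none", 8.0 + i, 16.0, 12.0) for i in range(4)]
        rows += [subject_row(i + 4, "aminophylline", 9.0 + i, 15.0, 11.0)
                 for i in range(4)]
        summary = summarize_cohort(make_cohort(rows))
        cols = set(summary.table.columns)
        expected = {"group", "n", "n_delayed"}
        for m in SUMMARY_METRICS:
            expected |= {f"{m}_mean", f"{m}_sd"}
        assert cols == expected
        assert set(summary.between_group) == set(SUMMARY_METRICS)
        assert summary.delayed_fisher is not None

    def test_single_group_has_no_between_tests(self):
        rows = [subject_row(i, "none", 8.0 + i, 16.0, 12.0) for i in range(4)]
        summary = summarize_cohort(make_cohort(rows))
        assert summary.between_group == {}
        assert "single group" in format_report(summary)

    def test_duplicate_subjects_rejected(self):
        rows = [subject_row(1, "none", 8, 16, 12), subject_row(1, "none", 8, 16, 12)]
        rows += [subject_row(2, "aminophylline", 8, 16, 12)]
        with pytest.raises(InputError):
            summarize_cohort(make_cohort(rows))

    def test_tiny_group_rejected(self):
        rows = [subject_row(1, "none", 8, 16, 12)]
        with pytest.raises(InsufficientDataError):
            summarize_cohort(make_cohort(rows))

    def test_missing_column_rejected(self):
        df = make_cohort([subject_row(1, "none", 8, 16, 12),
                          subject_row(2, "none", 8, 16, 12)])
        with pytest.raises(InputError):
            summarize_cohort(df.drop(columns=["mpri_recov"]))
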