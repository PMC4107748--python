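"""Frequency tables, logistic MLE vs 2x2 oracle, Wilcoxon exact path."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ddcnv.association import (
    build_frequency_table,
    compare_reference_frequencies,
    logistic_association,
    prevalence,
    wilcoxon_bp_by_genotype,
)
from ddcnv.cnv_calling import CopyNumberCall


def _call(sample, integer=None, status="called", assay="A1"):
    return CopyNumberCall(sample_id=sample, assay_id=assay, cn_hat=2.0,
                          ci_low=1.9, ci_high=2.1,
                          integer_call=integer, status=status)


def _calls_from_counts(counts, cohort):
    calls = []
    idx = cohort.set_index("subject_id")
    for sid in cohort["subject_id"]:
        calls.append(_call(sid, integer=int(idx.loc[sid, "true_cn"])))
    return calls


class TestPrevalence:
    @pytest.mark.parametrize("carriers,total,expected", [
        (12, 95, 12.6),
        (2, 92, 2.2),
        (0, 92, 0.0),
        (35, 172, 20.3),
    ])
    def test_one_decimal_reporting(self, carriers, total, expected):
        assert prevalence(carriers, total) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prevalence(1, 0)
        with pytest.raises(ValueError):
            prevalence(5, 4)


class TestFrequencyTable:
    def test_reproduces_published_deletion_counts(self, published_counts,
                                                  two_group_cohort):
        calls = _calls_from_counts(published_counts, two_group_cohort)
        table = build_frequency_table(calls, two_group_cohort)
        assert table.counts.loc["high", 1] == 12
        assert table.counts.loc["high", 2] == 83
        assert table.counts.loc["low", 1] == 2
        assert table.counts.loc["low", 2] == 90
        pct = table.percentages()
        assert pct.loc["high", 1] == 12.6 and pct.loc["high", 2] == 87.4
        assert pct.loc["low", 1] == 2.2 and pct.loc["low", 2] == 97.8
        assert not table.monomorphic

    def test_percentages_sum_to_100_within_rounding(self, published_counts,
                                                    two_group_cohort):
        calls = _calls_from_counts(published_counts, two_group_cohort)
        pct = build_frequency_table(calls, two_group_cohort).percentages()
        assert (abs(pct.sum(axis=1) - 100.0) <= 0.2).all()

    def test_excluded_samples_leave_denominator(self, published_counts,
                                                two_group_cohort):
        calls = _calls_from_counts(published_counts, two_group_cohort)
        calls[0] = _call(calls[0].sample_id, status="excluded")
        table = build_frequency_table(calls, two_group_cohort)
        assert int(table.counts.to_numpy().sum()) == len(calls) - 1

    def test_monomorphic_flagged(self, two_group_cohort):
        calls = [_call(s, integer=2) for s in two_group_cohort["subject_id"]]
        table = build_frequency_table(calls, two_group_cohort)
        assert table.monomorphic
        assert (table.percentages()[2] == 100.0).all()

    def test_orphan_sample_raises(self, two_group_cohort):
        with pytest.raises(ValueError):
            build_frequency_table([_call("ghost", 2)], two_group_cohort)


class TestLogisticAssociation:
    def test_single_predictor_equals_crossproduct_or(self, published_counts):
        rows = []
        for (group, cn), count in published_counts.items():
            rows += [dict(group=group, carrier=int(cn == 1))] * count
        res = logistic_association(pd.DataFrame(rows), "carrier", covariates=())
        expected = (12 * 90) / (83 * 2)
        assert res.status == "converged"
        assert res.odds_ratio == pytest.approx(expected, abs=1e-6)
        assert res.or_ci_low < res.odds_ratio < res.or_ci_high

    def test_null_genotype_gives_or_one(self):
        rows = ([dict(group="high", carrier=1)] * 10
                + [dict(group="high", carrier=0)] * 40
                + [dict(group="low", carrier=1)] * 10
                + [dict(group="low", carrier=0)] * 40)
        res = logistic_association(pd.DataFrame(rows), "carrier", covariates=())
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_reported_not_divergent(self):
        rows = ([dict(group="high", carrier=1)] * 20
                + [dict(group="low", carrier=0)] * 20
                + [dict(group="high", carrier=1)] * 2
                + [dict(group="low", carrier=0)] * 2)
        res = logistic_association(pd.DataFrame(rows), "carrier", covariates=())
        assert res.status == "separation"
        assert math.isnan(res.odds_ratio)

    def test_covariate_adjustment_runs(self, two_group_cohort):
        df = two_group_cohort.copy()
        df["carrier"] = (df["true_cn"] == 1).astype(int)
        res = logistic_association(df, "carrier", covariates=("age", "bmi", "sex"))
        assert res.covariates == ("age", "bmi", "sex")
        assert res.status in ("converged", "separation")

    def test_constant_predictor_raises(self):
        rows = [dict(group=g, carrier=1) for g in ["high"] * 5 + ["low"] * 5]
        with pytest.raises(ValueError):
            logistic_association(pd.DataFrame(rows), "carrier", covariates=())

    def test_tiny_groups_raise(self):
        rows = [dict(group="high", carrier=1), dict(group="low", carrier=0)]
        with pytest.raises(ValueError):
            logistic_association(pd.DataFrame(rows), "carrier", covariates=())


class TestWilcoxon:
    def test_enumeration_example(self):
        _, p = wilcoxon_bp_by_genotype([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_bp_by_genotype([5.0, 5.0, 7.0], [7.0, 5.0, 5.0])
        assert p == 1.0

    def test_exact_path_matches_scipy_exact_oracle(self, rng):
        """For tie-free samples with n, m <= 6 the enumeration agrees with
        scipy's recurrence-based exact Mann-Whitney p-value."""
        for trial in range(100):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            pooled = rng.permutation(np.arange(n + m, dtype=float) * 1.7 + 0.3)
            a, b = pooled[:n], pooled[n:]
            _, p = wilcoxon_bp_by_genotype(a, b)
            oracle = mannwhitneyu(a, b, alternative="two-sided",
                                  method="exact").pvalue
            assert p == pytest.approx(float(oracle), abs=1e-12)

    def test_exact_path_handles_ties(self):
        # hand enumeration: pooled [1,1,2,2], group A = [1,1]
        # midranks (1.5,1.5,3.5,3.5); W_A = 3, mu = 5; |dev| = 2
        # assignments of 2 of 4 ranks: sums {3,5,5,5,5,7}; |dev|>=2 in 2/6
        _, p = wilcoxon_bp_by_genotype([1.0, 1.0], [2.0, 2.0])
        assert p == pytest.approx(1 / 3)

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        _, p = wilcoxon_bp_by_genotype(a, b)
        assert p < 1e-4
        _, p_null = wilcoxon_bp_by_genotype(a, rng.normal(0, 1, 30))
        assert 0.0 <= p_null <= 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_bp_by_genotype([], [1.0])


class TestReferenceComparison:
    OBSERVED = pd.DataFrame([
        dict(cnv_id="esv27061", loss_pct=7.4, gain_pct=0.0),
        dict(cnv_id="esv2757747", loss_pct=7.4, gain_pct=0.0),
    ])
    REFERENCE = pd.DataFrame([
        dict(cnv_id="esv27061", loss_freq=1.0, gain_freq=5.8, source_n=270),
        dict(cnv_id="esv2757747", loss_freq=1.0, gain_freq=0.8, source_n=270),
    ])

    def test_gain_deficit_against_catalogue(self):
        out = compare_reference_frequencies(self.OBSERVED, self.REFERENCE)
        assert out.loc[0, "gain_diff"] == -5.8
        assert out.loc[1, "gain_diff"] == -0.8

    def test_identical_frequencies_zero_differences(self):
        ref = pd.DataFrame([dict(cnv_id="esv27061", loss_freq=7.4,
                                 gain_freq=0.0, source_n=1)])
        out = compare_reference_frequencies(self.OBSERVED.iloc[:1], ref)
        assert out.loc[0, "loss_diff"] == 0.0 and out.loc[0, "gain_diff"] == 0.0

    def test_missing_reference_row_raises(self):
        with pytest.raises(KeyError):
            compare_reference_frequencies(self.OBSERVED, self.REFERENCE.iloc[:1])
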