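"""Copy-number ratio, integer calling rule, repeat resolution."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddcnv.cnv_calling import (
    CopyNumberCall,
    ReferenceFailureError,
    call_estimates_frame,
    call_integer,
    call_wells,
    cn_ratio,
    exclusion_rate,
    resolve_sample,
)
from ddcnv.quantification import ConcentrationEstimate, estimate_lambda, quantify_wells
from ddcnv.synthetic_data import WellSimConfig, simulate_well


def _est(lam, k=5000, n=14000):
    lo = max(0.0, lam * 0.95)
    return ConcentrationEstimate(lambda_hat=lam, ci_low=lo, ci_high=lam * 1.05,
                                 k=k, n=n)


def _call(status, integer=None, sample="S1", cn=float("nan")):
    return CopyNumberCall(sample_id=sample, assay_id="A1", cn_hat=cn,
                          ci_low=0.9, ci_high=1.1,
                          integer_call=integer, status=status)


class TestCnRatio:
    def test_diploid_identity_exact(self):
        x = estimate_lambda(5000, 14000)
        cn, _ = cn_ratio(x, x)
        assert cn == 2.0

    def test_hemizygous_deletion(self):
        cn, _ = cn_ratio(_est(0.25), _est(0.5))
        assert cn == pytest.approx(1.0)

    def test_closed_form_ratio(self):
        cn, _ = cn_ratio(_est(0.33), _est(0.44))
        assert cn == pytest.approx(1.5)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        base_t, base_r = _est(0.3), _est(0.6)
        cn1, _ = cn_ratio(base_t, base_r)
        cn2, _ = cn_ratio(_est(0.3 * c), _est(0.6 * c))
        assert cn2 == pytest.approx(cn1, rel=1e-12)

    def test_reference_failure(self):
        zero = estimate_lambda(0, 14000)
        with pytest.raises(ReferenceFailureError):
            cn_ratio(_est(0.3), zero)

    def test_zero_target_yields_cn_zero(self):
        cn, (lo, hi) = cn_ratio(estimate_lambda(0, 14000), _est(0.5))
        assert cn == 0.0 and lo == 0.0 and hi > 0.0

    def test_ci_brackets_estimate(self):
        cn, (lo, hi) = cn_ratio(_est(0.25), _est(0.5))
        assert lo < cn < hi


class TestCallInteger:
    @pytest.mark.parametrize("cn,ci,status,integer", [
        (1.05, (0.91, 1.19), "called", 1),
        (1.5, (1.2, 1.8), "no_integer", None),
        (1.6, (0.9, 2.1), "ambiguous", None),
        (2.0, (1.99, 2.01), "called", 2),
        (4.2, (3.9, 4.5), "no_integer", None),  # above the 1-3 universe
    ])
    def test_rule_examples(self, cn, ci, status, integer):
        call = call_integer(cn, ci)
        assert call.status == status
        assert call.integer_call == integer

    def test_inverted_interval_raises(self):
        with pytest.raises(ValueError):
            call_integer(1.0, (1.2, 0.8))

    @given(st.floats(min_value=0.0, max_value=5.0),
           st.floats(min_value=0.0, max_value=3.0))
    def test_total_and_matches_enumeration_oracle(self, lo, width):
        """Every valid interval maps to exactly one status, and the status
        agrees with brute-force enumeration of integers in the interval."""
        hi = lo + width
        call = call_integer((lo + hi) / 2, (lo, hi))
        inside = [m for m in (1, 2, 3) if lo <= m <= hi]
        expected = {0: "no_integer", 1: "called"}.get(len(inside), "ambiguous")
        assert call.status == expected
        if expected == "called":
            assert call.integer_call == inside[0]
            assert call.ci_low <= call.integer_call <= call.ci_high

    def test_max_cn_extends_universe(self):
        assert call_integer(4.0, (3.9, 4.1), max_cn=5).integer_call == 4


class TestResolveSample:
    def test_concordant_repeats(self):
        out = resolve_sample([_call("called", 1), _call("called", 1)])
        assert out.status == "called" and out.integer_call == 1
        assert out.n_repeats == 2

    def test_repeated_failures_excluded(self):
        out = resolve_sample([_call("no_integer"), _call("no_integer")])
        assert out.status == "excluded"

    def test_discordant_calls_excluded(self):
        out = resolve_sample([_call("called", 1), _call("called", 2)])
        assert out.status == "excluded"

    def test_later_call_resolves_earlier_failure(self):
        out = resolve_sample([_call("no_integer"), _call("called", 2)])
        assert out.status == "called" and out.integer_call == 2

    def test_single_unresolved_attempt_passes_through(self):
        out = resolve_sample([_call("no_integer")])
        assert out.status == "no_integer" and out.n_repeats == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            resolve_sample([])

    def test_mixed_samples_raise(self):
        with pytest.raises(ValueError):
            resolve_sample([_call("called", 1, sample="A"),
                            _call("called", 1, sample="B")])


class TestExclusionRate:
    @pytest.mark.parametrize("excl,total,expected", [
        (14, 188, 7.4),
        (7, 188, 3.7),
        (1, 188, 0.5),
        (0, 188, 0.0),
    ])
    def test_reporting_percentages(self, excl, total, expected):
        assert exclusion_rate(excl, total) == expected

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            exclusion_rate(1, 0)
        with pytest.raises(ValueError):
            exclusion_rate(5, 4)


class TestCallWells:
    def _wells(self, true_cn, seed, n=12000, reps=2, sample="S1"):
        cfg = WellSimConfig(n_droplets=n, lambda_reference=0.5, true_cn=true_cn)
        return [
            simulate_well(cfg, sample_id=sample, replicate=r,
                          rng=np.random.default_rng(seed + r))
            for r in range(1, reps + 1)
        ]

    @pytest.mark.parametrize("true_cn", [1, 2, 3])
    def test_recovers_simulated_copy_number(self, true_cn):
        calls = call_wells(self._wells(true_cn, seed=100 * true_cn))
        assert len(calls) == 1
        assert calls[0].status == "called"
        assert calls[0].integer_call == true_cn

    def test_estimates_frame_path_agrees_with_well_path(self):
        wells = self._wells(1, seed=5) + self._wells(3, seed=9, sample="S2")
        via_wells = call_wells(wells)
        via_frame = call_estimates_frame(quantify_wells(wells))
        assert via_frame == via_wells

    def test_saturated_target_flagged(self):
        from ddcnv.quantification import DropletWell
        w = DropletWell("S1", "A1", "w1", 1, 1000, 1000, 500)
        calls = call_wells([w])
        assert calls[0].status == "saturated"
        assert math.isnan(calls[0].cn_hat)

    def test_dead_reference_flagged_failed(self):
        from ddcnv.quantification import DropletWell
        w = DropletWell("S1", "A1", "w1", 1, 1000, 300, 0)
        assert call_wells([w])[0].status == "failed_amplification"
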