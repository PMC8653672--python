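"""Cut-off statistics: frozen hand oracles, counting oracle, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biochipscreen import (
    InsufficientDataError,
    ValidationConfig,
    classify,
    count_errors,
    cutoff_Fm,
    decide_ccbeta,
    threshold_T,
)


def two_pass_mean_sd(values):
    """Independent two-pass mean/SD oracle (n-1 denominator), pure Python."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


class TestThresholdT:
    def test_zero_variance(self):
        assert threshold_T([3000, 3000, 3000]) == 3000

    def test_hand_computed(self):
        # mean 4000, sd sqrt(80000/3) = 163.2993; 4000 - 1.6*sd = 3738.7211
        assert threshold_T([4000, 4200, 3800, 4000], 1.6) == pytest.approx(
            3738.721094, abs=1e-6
        )

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            threshold_T([4000.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(10, 10000), min_size=2, max_size=50),
        st.floats(0.1, 3),
    )
    def test_matches_two_pass_oracle(self, values, factor):
        mean, sd = two_pass_mean_sd(values)
        expected = mean - factor * sd
        got = threshold_T(values, factor)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestCutoffFm:
    def test_zero_variance(self):
        assert cutoff_Fm([400, 400]) == 400

    def test_hand_computed(self):
        # mean 300, sd sqrt(5000/3) = 40.8248290; 300 + 1.64*sd = 366.9527196
        assert cutoff_Fm([300, 350, 250, 300], 1.64) == pytest.approx(
            366.9527196, abs=1e-6
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(10, 10000), min_size=2, max_size=50))
    def test_never_below_mean(self, values):
        assert cutoff_Fm(values) >= np.mean(values) - 1e-9

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(10, 10000), min_size=2, max_size=50),
        st.floats(0.1, 3),
    )
    def test_matches_two_pass_oracle(self, values, factor):
        mean, sd = two_pass_mean_sd(values)
        assert cutoff_Fm(values, factor) == pytest.approx(
            mean + factor * sd, rel=1e-9, abs=1e-9
        )


class TestClassify:
    def test_below_cutoff_positive(self):
        # reported SDZ Fm of the validation study
        assert classify(100.0, 406.78) == "positive"

    def test_at_cutoff_negative(self):
        assert classify(406.78, 406.78) == "negative"

    def test_far_above_negative(self):
        assert classify(10000.0, 406.78) == "negative"

    def test_vectorised(self):
        calls = classify(np.array([100.0, 406.78, 500.0]), 406.78)
        assert list(calls) == ["positive", "negative", "negative"]


class TestCountErrors:
    def test_one_spiked_at_cutoff_is_false_negative(self):
        spiked = [300.0] * 19 + [500.0]
        ec = count_errors([4000.0] * 20, spiked, cutoff=500.0, rule_label="Fm")
        assert ec.false_negative == 1
        assert ec.fn_rate == 5.0

    def test_three_blanks_below_threshold(self):
        blanks = [4000.0] * 17 + [100.0, 120.0, 90.0]
        ec = count_errors(blanks, [300.0] * 20, cutoff=3000.0, rule_label="T")
        assert ec.false_positive == 3
        assert ec.fp_rate == 15.0

    def test_cutoff_below_everything(self):
        ec = count_errors([4000.0] * 20, [300.0] * 20, cutoff=10.0, rule_label="Fm")
        assert ec.false_positive == 0
        assert ec.false_negative == 20

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            count_errors([1.0, 2.0], [1.0, 2.0], math.inf, "Fm")

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0, 10000), min_size=1, max_size=40),
        st.lists(st.floats(0, 10000), min_size=1, max_size=40),
        st.floats(0, 10000),
    )
    def test_matches_naive_loop(self, blanks, spiked, cutoff):
        ec = count_errors(blanks, spiked, cutoff, "Fm")
        assert ec.false_positive == sum(1 for b in blanks if b < cutoff)
        assert ec.false_negative == sum(1 for s in spiked if s >= cutoff)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0, 10000), min_size=1, max_size=40),
        st.lists(st.floats(0, 10000), min_size=1, max_size=40),
        st.floats(0, 10000),
        st.floats(0, 2000),
    )
    def test_monotone_in_cutoff(self, blanks, spiked, cutoff, bump):
        """Raising the cut-off weakly raises FP and weakly lowers FN."""
        lo = count_errors(blanks, spiked, cutoff, "Fm")
        hi = count_errors(blanks, spiked, cutoff + bump, "Fm")
        assert hi.false_positive >= lo.false_positive
        assert hi.false_negative <= lo.false_negative


class TestDecideCcbeta:
    @pytest.fixture()
    def cfg(self):
        return ValidationConfig()

    def _errors(self, analyte, fn, rule="Fm"):
        return count_errors(
            [4000.0] * 20, [300.0] * (20 - fn) + [9000.0] * fn,
            cutoff=500.0, rule_label=rule, analyte=analyte,
        )

    def test_tmpm_one_false_negative_validates(self, panel, cfg):
        d = decide_ccbeta(self._errors("TMPM", 1), panel["TMPM"], cfg)
        assert d.decision == "validated"
        assert d.cc_beta == 10
        assert d.below_mrl is True

    def test_sdim_zero_false_negatives_validates(self, panel, cfg):
        d = decide_ccbeta(self._errors("SDIM", 0), panel["SDIM"], cfg)
        assert d.decision == "validated"
        assert d.cc_beta == 20

    def test_two_false_negatives_escalate(self, panel, cfg):
        d = decide_ccbeta(self._errors("SDZ", 2), panel["SDZ"], cfg)
        assert d.decision == "escalate"
        assert d.cc_beta is None and d.below_mrl is None

    def test_prohibited_substance_uses_screening_target(self, panel, cfg):
        d = decide_ccbeta(self._errors("DAP", 0), panel["DAP"], cfg)
        assert d.below_mrl is True  # 20 <= screening target 20

    def test_mismatched_analyte_rejected(self, panel, cfg):
        with pytest.raises(ValueError, match="TMPM"):
            decide_ccbeta(self._errors("TMPM", 0), panel["SDZ"], cfg)

    def test_t_rule_counts_rejected(self, panel, cfg):
        with pytest.raises(ValueError, match="Fm"):
            decide_ccbeta(self._errors("SDZ", 0, rule="T"), panel["SDZ"], cfg)


class TestSeparationAlgebra:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_separated_cohorts_imply_t_above_fm(self, seed):
        """If the gap between cohort means exceeds t*sd_b + fm*sd_s, T > Fm."""
        rng = np.random.default_rng(seed)
        spiked = rng.uniform(200, 600, 20)
        blanks = rng.uniform(3000, 6000, 20)
        gap = blanks.mean() - spiked.mean()
        margin = 1.6 * blanks.std(ddof=1) + 1.64 * spiked.std(ddof=1)
        assert gap > margin  # construction guarantees separation
        assert threshold_T(blanks, 1.6) > cutoff_Fm(spiked, 1.64)


def test_reported_validation_magnitudes_satisfy_validity():
    """The study's printed T/Fm pairs all pass the T > Fm check."""
    t_values = [4282.65, 2961.23, 6664.50, 2678.30, 2722.14, 6235.40, 3186.33,
                2337.10, 5598.27, 1706.54, 3049.47, 6689.48, 4207.31, 2421.01, 1292.80]
    fm_values = [406.78, 825.57, 614.27, 380.34, 291.84, 268.31, 280.70,
                 419.48, 438.78, 572.06, 473.66, 1178.84, 826.78, 431.28, 260.65]
    assert all(t > fm for t, fm in zip(t_values, fm_values))
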