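import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from discountfit import (ParamVector, TrialRecord, choice_probability,
                         dataset_log_likelihood, subjective_value)
from discountfit.likelihood import P_FLOOR


class TestChoiceProbability:
    def test_equal_values_give_half(self):
        assert choice_probability(20.0, 20.0, 1.5) == pytest.approx(0.5)

    def test_logistic_quartile_point(self):
        # value gap of beta*ln(3) forces p = 0.75 for any beta
        for beta in (0.3, 1.0, 4.0):
            p = choice_probability(20.0, 20.0 + beta * math.log(3.0), beta)
            assert p == pytest.approx(0.75, abs=1e-12)

    def test_direct_evaluation(self):
        p = choice_probability(20.0, 30.0, 1.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-10.0)), rel=1e-12)

    def test_conventions_are_reciprocal(self):
        p_temp = choice_probability(20.0, 25.0, 2.0, "temperature")
        p_mult = choice_probability(20.0, 25.0, 0.5, "multiplier")
        assert p_temp == pytest.approx(p_mult)

    def test_larger_temperature_is_noisier(self):
        # fixed positive value gap: p(LL) decays towards 0.5 as beta grows
        ps = [choice_probability(20.0, 26.0, b) for b in (0.5, 2.0, 8.0, 1e6)]
        assert ps == sorted(ps, reverse=True)
        assert ps[-1] == pytest.approx(0.5, abs=1e-4)

    def test_no_overflow_for_extreme_gaps(self):
        assert choice_probability(20.0, 5000.0, 1e-3) == pytest.approx(1.0)
        assert choice_probability(5000.0, 20.0, 1e-3) == pytest.approx(0.0)

    def test_beta_domain_error(self):
        with pytest.raises(ValueError):
            choice_probability(20.0, 30.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(sv_ss=st.floats(0.1, 80), sv_ll=st.floats(0.1, 80),
           beta=st.floats(0.01, 50))
    def test_two_option_normalization(self, sv_ss, sv_ll, beta):
        p = choice_probability(sv_ss, sv_ll, beta)
        q = choice_probability(sv_ll, sv_ss, beta)
        assert p + q == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= p <= 1.0  # may round to the endpoints for huge gaps


class TestDatasetLogLikelihood:
    def test_all_half_probabilities(self):
        # at sv parity each trial contributes ln 0.5
        trials = [TrialRecord("s", 20.0, 40.0, 20.0, c)
                  for c in ["SS", "LL"] * 5]
        params = ParamVector("H", (0.05,), 1.0)  # kD=1 -> SV_LL = 20 = SS
        out = dataset_log_likelihood(trials, "H", params)
        assert out.loglik == pytest.approx(10 * math.log(0.5))
        assert out.n_trials == 10

    def test_near_deterministic_limit(self):
        trials = [TrialRecord("s", 20.0, 80.0, 1.0, "LL")]
        params = ParamVector("H", (1e-6,), 0.01)
        out = dataset_log_likelihood(trials, "H", params)
        assert -1e-9 < out.loglik <= 0.0

    def test_hand_summed_toy_oracle(self, toy_trials):
        params = ParamVector("H", (0.01,), 2.0)
        expected = 0.0
        for t in toy_trials:
            sv = subjective_value("H", [0.01], t.amount_ll, t.delay_ll)
            p_ll = 1.0 / (1.0 + math.exp(-(sv - 20.0) / 2.0))
            expected += math.log(p_ll if t.choice == "LL" else 1.0 - p_ll)
        out = dataset_log_likelihood(toy_trials, "H", params)
        assert out.loglik == pytest.approx(expected, rel=1e-12)

    def test_order_invariance(self, h_agent_trials):
        params = ParamVector("H", (0.02,), 1.0)
        fwd = dataset_log_likelihood(h_agent_trials, "H", params).loglik
        rev = dataset_log_likelihood(h_agent_trials[::-1], "H", params).loglik
        assert fwd == pytest.approx(rev, rel=1e-14)

    def test_floor_bounds_loglik(self):
        trials = [TrialRecord("s", 20.0, 21.0, 180.0, "LL")] * 5
        params = ParamVector("H", (5.0,), 1e-3)  # LL choice hugely unlikely
        out = dataset_log_likelihood(trials, "H", params)
        assert out.loglik >= 5 * math.log(P_FLOOR)

    def test_consistent_chooser_improves_as_beta_shrinks(self):
        # choices always match the value-difference sign: smaller beta
        # sharpens the sigmoid and raises the likelihood
        trials = [TrialRecord("s", 20.0, 60.0, 7.0, "LL"),
                  TrialRecord("s", 20.0, 21.0, 180.0, "SS")] * 3
        lls = [dataset_log_likelihood(
            trials, "H", ParamVector("H", (0.02,), b)).loglik
            for b in (4.0, 1.0, 0.25, 0.05)]
        assert lls == sorted(lls)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            dataset_log_likelihood([], "H", ParamVector("H", (0.05,), 1.0))


def test_trial_record_validation():
    with pytest.raises(ValueError):
        TrialRecord("s", 20.0, 19.0, 5.0, "LL")  # LL not larger
    with pytest.raises(ValueError):
        TrialRecord("s", 20.0, 30.0, 0.0, "LL")  # no delay
    with pytest.raises(ValueError):
        TrialRecord("s", 20.0, 30.0, 5.0, "yes")
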