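import numpy as np
import pytest

from discountfit import (AgentSpec, IndifferencePoint, fit_indifference_curve,
                         group_median_points, run_adaptive_session,
                         staircase_indifference, subjective_value)
from discountfit.cohort import ADAPTIVE_CRITERIA, ADAPTIVE_DELAYS, \
    StaircaseBlock, AdaptiveSession
from discountfit.likelihood import TrialRecord


def _session_with_bracket(bracket, delay=30.0, terminated=True):
    return AdaptiveSession("x", [StaircaseBlock(delay, 3.0, [], bracket,
                                                terminated)])


class TestStaircaseIndifference:
    def test_bracket_midpoint(self):
        pts = staircase_indifference(_session_with_bracket((41.0, 38.0)))
        assert pts[0].indifference_amount == pytest.approx(39.5)

    def test_fraction(self):
        pts = staircase_indifference(_session_with_bracket((41.0, 39.0)))
        assert pts[0].fraction == pytest.approx(20.0 / 40.0)

    def test_unterminated_delay_flagged_missing(self):
        sess = _session_with_bracket(None, terminated=False)
        assert staircase_indifference(sess) == [None]

    def test_noiseless_hyperbolic_agent_accuracy(self):
        # k=0.02 at 30 days: true indifference 20*(1+0.6) = 32; a
        # deterministic agent's terminal bracket straddles it, so the
        # midpoint lands within half the 3-euro criterion
        agent = AgentSpec("d", "H", (0.02,), 1e-8)
        sess = run_adaptive_session(agent, delays=(30.0,), criteria=(3.0,),
                                    seed=0)
        pt = staircase_indifference(sess)[0]
        assert pt is not None
        assert abs(pt.indifference_amount - 32.0) <= 1.5

    def test_noiseless_exponential_agent_long_delay(self):
        agent = AgentSpec("e", "E", (0.01,), 1e-8)
        sess = run_adaptive_session(agent, seed=0)
        pt = staircase_indifference(sess)[5]  # 90-day block
        assert pt is not None
        truth = 20.0 * np.exp(0.9)
        assert abs(pt.indifference_amount - truth) <= ADAPTIVE_CRITERIA[5]


class TestCurveFit:
    @staticmethod
    def _points(model_id, params, delays=(1, 2, 7, 14, 30, 90, 180)):
        return [IndifferencePoint(d, 20.0 / subjective_value(
            model_id, params, 1.0, d), subjective_value(model_id, params, 1.0, d))
            for d in delays]

    def test_exact_recovery_of_noiseless_hyperbola(self):
        pts = self._points("H", [0.01])
        fit = fit_indifference_curve(pts, "H", seed=0)
        assert fit.params[0] == pytest.approx(0.01, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_r_squared_matches_definition(self):
        rng = np.random.default_rng(4)
        fracs = np.clip([subjective_value("H", [0.02], 1.0, d) +
                         rng.normal(0, 0.05) for d in ADAPTIVE_DELAYS],
                        0.05, 1.0)
        pts = [IndifferencePoint(d, 20.0 / f, f)
               for d, f in zip(ADAPTIVE_DELAYS, fracs)]
        fit = fit_indifference_curve(pts, "H", seed=0)
        fitted = np.array([subjective_value("H", fit.params, 1.0, d)
                           for d in ADAPTIVE_DELAYS])
        ss_res = np.sum((fitted - fracs) ** 2)
        ss_tot = np.sum((fracs - np.mean(fracs)) ** 2)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-8)

    def test_flat_fractions_can_go_negative_unclipped(self):
        fracs = [0.62, 0.58, 0.61, 0.59, 0.60, 0.62, 0.58]
        pts = [IndifferencePoint(d, 20.0 / f, f)
               for d, f in zip(ADAPTIVE_DELAYS, fracs)]
        fit = fit_indifference_curve(pts, "E", seed=0)
        assert fit.r_squared <= 1.0  # reported as computed, however poor

    def test_dual_parameter_nesting_r_squared(self):
        rng = np.random.default_rng(9)
        fracs = np.clip([subjective_value("CS", [0.008, 0.5], 1.0, d) +
                         rng.normal(0, 0.04) for d in ADAPTIVE_DELAYS],
                        0.05, 1.0)
        pts = [IndifferencePoint(d, 20.0 / f, f)
               for d, f in zip(ADAPTIVE_DELAYS, fracs)]
        r2 = {m: fit_indifference_curve(pts, m, seed=1).r_squared
              for m in ("H", "E", "GM", "R", "CS")}
        assert r2["GM"] >= r2["H"] - 1e-8
        assert r2["R"] >= r2["H"] - 1e-8
        assert r2["CS"] >= r2["E"] - 1e-8

    def test_underdetermined_error(self):
        pts = self._points("H", [0.01])[:2]
        with pytest.raises(ValueError, match="at least"):
            fit_indifference_curve(pts, "GM")


class TestGroupMedians:
    def test_odd_count_median(self):
        cohort = {f"s{i}": [IndifferencePoint(30.0, 20.0 / f, f)]
                  for i, f in enumerate((0.2, 0.5, 0.8))}
        med = group_median_points(cohort)
        assert med[0].fraction == pytest.approx(0.5)

    def test_even_count_uses_central_mean(self):
        cohort = {f"s{i}": [IndifferencePoint(30.0, 20.0 / f, f)]
                  for i, f in enumerate((0.2, 0.4, 0.6, 0.8))}
        med = group_median_points(cohort)
        assert med[0].fraction == pytest.approx(0.5)

    def test_mixed_grids_rejected(self):
        cohort = {
            "six": [IndifferencePoint(d, 40.0, 0.5) for d in (1, 2, 7, 14, 30, 90)],
            "seven": [IndifferencePoint(d, 40.0, 0.5) for d in ADAPTIVE_DELAYS],
        }
        with pytest.raises(ValueError, match="grid"):
            group_median_points(cohort)
        # splitting by grid size, as for six- vs seven-point subsets, works
        assert len(group_median_points({"six": cohort["six"]})) == 6
        assert len(group_median_points({"seven": cohort["seven"]})) == 7
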