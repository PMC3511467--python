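import io

import numpy as np
import pytest

from discountfit import (AgentSpec, CohortConfig, generate_cohort_dataset,
                         generate_fixed_offer_set, population_preset,
                         run_adaptive_session, simulate_choice,
                         subjective_value, write_trials)
from discountfit.cohort import (ADAPTIVE_CRITERIA, ADAPTIVE_DELAYS,
                                FIXED_DELAYS, MIN_LL_AMOUNT)


class TestSimulateChoice:
    def test_indifferent_offer_splits_evenly(self):
        # LL amount chosen so SV_LL == 20 exactly: kD=1 and amount 2*20
        agent = AgentSpec("a", "H", (0.05,), 1.5)
        rng = np.random.default_rng(0)
        n = 10_000
        ll = sum(simulate_choice(agent, 40.0, 20.0, rng) == "LL"
                 for _ in range(n))
        assert abs(ll / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_beta_to_zero_is_value_maximizer(self):
        agent = AgentSpec("a", "H", (0.05,), 1e-9)
        rng = np.random.default_rng(0)
        assert simulate_choice(agent, 41.0, 20.0, rng) == "LL"
        assert simulate_choice(agent, 39.0, 20.0, rng) == "SS"

    def test_logistic_refit_recovers_beta(self):
        # fit a plain logistic to simulated choices vs value difference
        from scipy.optimize import minimize_scalar

        agent = AgentSpec("a", "H", (0.02,), 1.5)
        rng = np.random.default_rng(3)
        amounts = rng.uniform(20.5, 80, size=500)
        delays = rng.choice(ADAPTIVE_DELAYS, size=500)
        sv = subjective_value("H", [0.02], amounts, delays)
        chose = np.array([simulate_choice(agent, a, d, rng) == "LL"
                          for a, d in zip(amounts, delays)])

        def nll(beta):
            p = 1.0 / (1.0 + np.exp(-(sv - 20.0) / beta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(np.where(chose, np.log(p), np.log(1 - p)))

        beta_hat = minimize_scalar(nll, bounds=(0.05, 20), method="bounded").x
        assert abs(beta_hat - 1.5) / 1.5 < 0.2


class TestAdaptiveSession:
    def test_trial_schema_honours_task_limits(self):
        agent = AgentSpec("a", "H", (0.03,), 2.0)
        sess = run_adaptive_session(agent, seed=5)
        assert len(sess.blocks) == 7
        for t in sess.trials:
            assert t.amount_ss == 20.0
            assert t.amount_ll >= MIN_LL_AMOUNT

    def test_terminal_gap_within_criterion(self):
        agent = AgentSpec("a", "H", (0.03,), 2.0)
        sess = run_adaptive_session(agent, seed=5)
        for block, crit in zip(sess.blocks, ADAPTIVE_CRITERIA):
            if block.terminated:
                lo_acc, hi_rej = block.bracket
                assert lo_acc - hi_rej <= crit + 1e-9

    def test_reproducible_under_seed(self):
        agent = AgentSpec("a", "GM", (0.1, 0.5), 2.0)
        t1 = run_adaptive_session(agent, seed=9).trials
        t2 = run_adaptive_session(agent, seed=9).trials
        assert [(t.amount_ll, t.choice) for t in t1] == \
            [(t.amount_ll, t.choice) for t in t2]

    def test_delay_criteria_alignment_enforced(self):
        agent = AgentSpec("a", "H", (0.03,), 2.0)
        with pytest.raises(ValueError):
            run_adaptive_session(agent, delays=(1.0, 2.0), criteria=(1.0,))


class TestFixedOffers:
    def test_bounds_and_split(self):
        offers = generate_fixed_offer_set(0.01, delays=(30.0,),
                                          n_per_delay=40, seed=0)
        amounts = np.array([a for _, a, _ in offers])
        assert np.all((amounts >= 20.5) & (amounts <= 80.0))
        # A* = 20*(1+0.01*30) = 26: half below, half above
        assert (amounts <= 26.0).sum() == 20
        assert (amounts >= 26.0).sum() == 20

    def test_clipped_indifference_flags_degenerate_arm(self):
        # k=0.05 at 180d: A* = 200 clipped to 80, "above" arm collapses
        offers = generate_fixed_offer_set(0.05, delays=(180.0,),
                                          n_per_delay=10, seed=0)
        above = [(a, flag) for _, a, flag in offers if a >= 80.0]
        assert len(above) == 5
        assert all(flag for _, flag in above)
        assert all(a == 80.0 for a, _ in above)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            generate_fixed_offer_set(-0.1, n_per_delay=10)
        with pytest.raises(ValueError):
            generate_fixed_offer_set(0.01, n_per_delay=7)


class TestCohortGeneration:
    def test_cardinality(self):
        cfg = CohortConfig(n_agents=5, model_mix="H", seed=0)
        dataset, truth, sessions = generate_cohort_dataset(cfg)
        assert len(dataset) == len(truth) == len(sessions) == 5
        assert all(len(s.blocks) == 7 for s in sessions.values())

    def test_byte_identical_outputs_under_seed(self):
        cfg = CohortConfig(n_agents=4, model_mix={"H": 1, "CS": 1}, seed=3)
        outs = []
        for _ in range(2):
            dataset, truth, _ = generate_cohort_dataset(cfg)
            buf = io.StringIO()
            write_trials(dataset, buf)
            outs.append((buf.getvalue(), truth.to_csv(index=False)))
        assert outs[0] == outs[1]

    def test_truth_never_in_trials(self):
        cfg = CohortConfig(n_agents=3, model_mix="CS", seed=1)
        dataset, truth, _ = generate_cohort_dataset(cfg)
        assert set(truth.columns) >= {"agent_id", "model_id", "a", "b", "beta"}
        for trials in dataset.values():
            assert {type(t).__name__ for t in trials} == {"TrialRecord"}

    def test_fixed_offer_task(self):
        cfg = CohortConfig(n_agents=3, model_mix="H", task="fixed_offers",
                           n_per_delay=10, seed=2)
        dataset, truth, sessions = generate_cohort_dataset(cfg)
        assert sessions == {}
        for trials in dataset.values():
            assert len(trials) == 10 * len(FIXED_DELAYS)
            assert {t.delay_ll for t in trials} == set(FIXED_DELAYS)

    def test_population_medians_match_calibration(self):
        # large draw: sample median of lognormal k near the preset median
        rng = np.random.default_rng(0)
        from discountfit.cohort import _draw_param
        for preset, expected in (("dataset1", 0.0083), ("gamblers", 0.0463)):
            triple = population_preset("H", preset)["k"]
            draws = [_draw_param("k", triple, rng) for _ in range(4000)]
            assert np.median(draws) == pytest.approx(expected, rel=0.1)

    def test_beta_median_override(self):
        table = population_preset("CS", "dataset2", beta_median=0.5)
        assert table["beta"][0] == 0.5
        assert table["a"] == population_preset("CS", "dataset2")["a"]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_agents=2, model_mix="XX")
        with pytest.raises(ValueError):
            CohortConfig(n_agents=2, preset="nope")
        with pytest.raises(ValueError):
            CohortConfig(n_agents=2, task="quiz")
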