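"""Validation studies: identities, oracles, parameter and model recovery.

These are the package's end-to-end checks that the analysis pipeline does
what it claims on data with known ground truth: algebraic nesting
identities among the discount functions, optimizer-vs-grid likelihood
comparisons, Monte-Carlo-vs-closed-form exceedance probabilities,
parameter and model recovery on calibrated synthetic cohorts, the
Hessian-correlation contrast between dual-parameter models, the R^2 vs
discount-rate confound, and type-I error calibration of the group tests.
Every study is seeded and returns plain dictionaries of measured numbers.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
from scipy.stats import spearmanr

from .bms import (bms_exceedance, exceedance_mc,
                  exceedance_two_model_closed_form,
                  log_evidence_from_scores)
from .cohort import AgentSpec, CohortConfig, generate_cohort_dataset, \
    run_adaptive_session
from .estimation import fit_cohort, fit_subject
from .groupstats import compare_parameter
from .indifference import fit_indifference_curve, staircase_indifference
from .likelihood import trials_to_arrays, P_FLOOR
from .models import BETA_BOUNDS, get_model, subjective_value
from .selection import scores_from_fits
from .uncertainty import cohort_mean_correlations

__all__ = [
    "identity_discrepancy",
    "mle_grid_gap",
    "bms_mc_vs_closed_form",
    "parameter_recovery_study",
    "model_recovery_study",
    "hessian_contrast_study",
    "r2_rate_confound_study",
    "type1_calibration_study",
]

RATE_COLUMN = {"H": "k", "E": "k", "GM": "k", "R": "k", "CS": "a"}


def identity_discrepancy(n_amounts: int = 100, n_delays: int = 100,
                         rates: Sequence[float] = (0.005, 0.05, 0.5)
                         ) -> Dict[str, float]:
    """Max |SV| discrepancy of the nesting identities on an (A, D) grid.

    CS(b=1, a=k) must equal E(k), and GM(s=1) and R(s=1) must equal H(k),
    over n_amounts x n_delays grid points for every rate supplied.
    """
    A, D = np.meshgrid(np.linspace(0.5, 80.0, n_amounts),
                       np.linspace(0.0, 180.0, n_delays))
    out = {"cs_vs_e": 0.0, "gm_vs_h": 0.0, "r_vs_h": 0.0}
    for k in rates:
        e = subjective_value("E", [k], A, D)
        h = subjective_value("H", [k], A, D)
        out["cs_vs_e"] = max(out["cs_vs_e"], float(np.max(np.abs(
            subjective_value("CS", [k, 1.0], A, D) - e))))
        out["gm_vs_h"] = max(out["gm_vs_h"], float(np.max(np.abs(
            subjective_value("GM", [k, 1.0], A, D) - h))))
        out["r_vs_h"] = max(out["r_vs_h"], float(np.max(np.abs(
            subjective_value("R", [k, 1.0], A, D) - h))))
    return out


def _grid_max_loglik(trials, model_id: str, n_axis: int = 40) -> float:
    """Exhaustive log-spaced lattice search over (rate, exponent, beta)."""
    spec = get_model(model_id)
    a_ss, a_ll, d_ll, chose_ll = trials_to_arrays(trials)
    axes = [np.geomspace(lo, hi, n_axis) for lo, hi in spec.default_bounds]
    betas = np.geomspace(*BETA_BOUNDS, n_axis)

    if spec.n_params == 1:
        param_grid = axes[0][:, None]
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        param_grid = np.column_stack([g0.ravel(), g1.ravel()])

    best = -np.inf
    for params in param_grid:
        sv_ll = subjective_value(model_id, params, a_ll, d_ll)
        diff = sv_ll - a_ss                                   # (n_trials,)
        z = diff[None, :] / betas[:, None]                    # (n_beta, n_trials)
        p_ll = np.clip(1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))),
                       P_FLOOR, 1.0 - P_FLOOR)
        p = np.where(chose_ll[None, :], p_ll, 1.0 - p_ll)
        best = max(best, float(np.max(np.sum(np.log(p), axis=1))))
    return best


def mle_grid_gap(seed: int = 0, n_trials: int = 30, n_axis: int = 40
                 ) -> Dict[str, float]:
    """Optimizer loglik vs exhaustive lattice max on toy subjects.

    Three 30-trial subjects are simulated (one GM, one R, one CS agent on
    the fixed-offer design) and fit with their generating model; the gap
    grid_max - fitted_loglik should never exceed ~0.01 (the multi-start
    optimizer must at least match a coarse exhaustive search).
    """
    rng = np.random.default_rng(seed)
    agents = [
        AgentSpec("toyGM", "GM", (0.08, 0.6), 1.5),
        AgentSpec("toyR", "R", (0.05, 0.75), 1.5),
        AgentSpec("toyCS", "CS", (0.01, 0.6), 1.5),
    ]
    gaps = {}
    for agent in agents:
        trials = []
        delays = (0.25, 1.0, 7.0, 30.0, 90.0, 180.0)
        for i in range(n_trials):
            d = delays[i % len(delays)]
            amt = float(rng.uniform(20.5, 80.0))
            sv = subjective_value(agent.model_id, agent.discount_params,
                                  amt, d)
            p_ll = 1.0 / (1.0 + np.exp(-(sv - 20.0) / agent.beta))
            choice = "LL" if rng.random() < p_ll else "SS"
            from .likelihood import TrialRecord
            trials.append(TrialRecord(agent.agent_id, 20.0, amt, d, choice))
        fit = fit_subject(trials, agent.model_id, seed=seed)
        grid_best = _grid_max_loglik(trials, agent.model_id, n_axis)
        gaps[agent.model_id] = grid_best - fit.loglik
    gaps["max_gap"] = max(gaps.values())
    return gaps


def bms_mc_vs_closed_form(seed: int = 0, n_matrices: int = 10,
                          n_subjects: int = 12,
                          mc_samples: int = 1_000_000) -> Dict[str, float]:
    """Monte-Carlo exceedance vs the exact two-model incomplete-beta form.

    For random two-model evidence matrices, the MC estimate must sit
    within 3 binomial standard errors of 1 - I_0.5(alpha1, alpha2).
    Returns the worst absolute error and worst error in SE units.
    """
    rng = np.random.default_rng(seed)
    max_abs = 0.0
    max_z = 0.0
    for i in range(n_matrices):
        lme = rng.normal(0.0, 2.0, size=(n_subjects, 2))
        res = bms_exceedance(lme, mc_samples=mc_samples,
                             seed=int(rng.integers(2 ** 31)),
                             use_closed_form=False)
        exact = exceedance_two_model_closed_form(res.alpha)
        err = abs(res.exceedance[0] - exact)
        se = max(np.sqrt(exact * (1 - exact) / mc_samples), 1e-12)
        max_abs = max(max_abs, float(err))
        max_z = max(max_z, float(err / se))
    return {"max_abs_error": max_abs, "max_se_units": max_z}


def parameter_recovery_study(seed: int = 0, n_agents: int = 50,
                             models: Sequence[str] = ("H", "E", "GM", "R", "CS"),
                             preset: str = "dataset2") -> Dict[str, Dict[str, float]]:
    """Fit each generating model to its own calibrated adaptive cohort.

    Per model: Spearman correlation of log true vs log estimated discount
    rate, the fraction of agents whose beta is recovered within a factor
    of 2, and the median trial count.
    """
    out: Dict[str, Dict[str, float]] = {}
    base = np.random.SeedSequence(seed).spawn(len(models))
    for m, ss in zip(models, base):
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        cfg = CohortConfig(n_agents=n_agents, model_mix=m, preset=preset,
                           seed=sub_seed)
        dataset, truth, _ = generate_cohort_dataset(cfg)
        fits = [fit_subject(dataset[a], m, seed=sub_seed + i)
                for i, a in enumerate(truth.agent_id)]
        true_rate = truth[RATE_COLUMN[m]].values
        est_rate = np.array([f.params.discount_params[0] for f in fits])
        ratio = np.array([f.params.beta for f in fits]) / truth.beta.values
        out[m] = {
            "rate_spearman": float(spearmanr(np.log(true_rate),
                                             np.log(est_rate)).statistic),
            "beta_within_factor2": float(np.mean((ratio > 0.5) & (ratio < 2.0))),
            "median_trials": float(np.median([len(dataset[a])
                                              for a in truth.agent_id])),
        }
    return out


def model_recovery_study(seed: int = 0, n_agents: int = 40,
                         n_replicates: int = 5,
                         generating_model: str = "CS",
                         beta_median: float = 0.5) -> Dict[str, object]:
    """BMS model recovery on low-noise cohorts of one generating model.

    Each replicate simulates a cohort, fits all five models to every
    agent, and runs BMS on the AIC-approximated evidences; reports the
    generating model's exceedance probability per replicate and how many
    replicates reach the decisive 0.95 threshold.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    exceedances: List[float] = []
    for ss in seeds:
        rep_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        cfg = CohortConfig(n_agents=n_agents, model_mix=generating_model,
                           beta_median=beta_median, seed=rep_seed)
        dataset, _, _ = generate_cohort_dataset(cfg)
        fits = fit_cohort(dataset, seed=rep_seed)
        table = scores_from_fits(fits)
        res = bms_exceedance(log_evidence_from_scores(table.scores.values),
                             seed=rep_seed)
        idx = list(table.scores.columns).index(generating_model)
        exceedances.append(float(res.exceedance[idx]))
    return {
        "exceedances": exceedances,
        "n_decisive": int(sum(x > 0.95 for x in exceedances)),
        "n_replicates": n_replicates,
    }


def hessian_contrast_study(seed: int = 0, n_agents: int = 20,
                           preset: str = "dataset2") -> Dict[str, float]:
    """Mean |rate-exponent| correlation for GM and R vs CS.

    Matched cohorts are generated from each dual-parameter model and fit
    with their own model; correlations come from inverse Hessians (CS with
    the 100*a rescue).  The expected pattern is a strong k-s dependency in
    GM and R and a weaker a-b dependency in CS.
    """
    out = {}
    seeds = np.random.SeedSequence(seed).spawn(3)
    for m, ss in zip(("GM", "R", "CS"), seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        cfg = CohortConfig(n_agents=n_agents, model_mix=m, preset=preset,
                           seed=sub_seed)
        dataset, truth, _ = generate_cohort_dataset(cfg)
        fits = [fit_subject(dataset[a], m, seed=sub_seed + i)
                for i, a in enumerate(truth.agent_id)]
        table = cohort_mean_correlations(fits, rescale_cs=(m == "CS"))
        out[f"abs_corr_{m}"] = float(abs(table.loc[m, "mean_corr"]))
        out[f"non_invertible_{m}"] = float(table.loc[m, "n_non_invertible"])
    return out


def r2_rate_confound_study(seed: int = 0, n_subjects: int = 100,
                           beta: float = 2.0,
                           k_range=(0.003, 0.1)) -> Dict[str, float]:
    """Spearman correlation between hyperbolic fit R^2 and the true rate k.

    Subjects with log-uniform k and fixed choice noise run the adaptive
    task; hyperbolic curves are fit to each subject's indifference points.
    Steeper discounters pull their points further from the flat mean line,
    so R^2 should correlate positively with k.
    """
    rng = np.random.default_rng(seed)
    ks, r2s = [], []
    for i in range(n_subjects):
        k = float(np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]))))
        agent = AgentSpec(f"s{i}", "H", (k,), beta)
        session = run_adaptive_session(agent, seed=int(rng.integers(2 ** 31)))
        points = [p for p in staircase_indifference(session) if p is not None]
        if len(points) < 3:
            continue
        fit = fit_indifference_curve(points, "H", seed=i)
        ks.append(k)
        r2s.append(fit.r_squared)
    rho = spearmanr(ks, r2s).statistic
    return {"spearman_r2_k": float(rho), "n_subjects": len(ks)}


def type1_calibration_study(seed: int = 0, n_replicates: int = 1000,
                            n1: int = 17, n2: int = 18,
                            alpha: float = 0.05) -> Dict[str, float]:
    """Empirical type-I error of the two-sample parameter comparison.

    Both groups are drawn from one log-normal parameter population (no
    true difference); the rejection rate of the square-root-transformed t
    test at alpha should match alpha up to binomial error.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = np.exp(rng.normal(np.log(0.0083), 0.8, size=n1))
        b = np.exp(rng.normal(np.log(0.0083), 0.8, size=n2))
        t_res, _ = compare_parameter(a, b, transform="sqrt")
        rejections += t_res.p_value < alpha
    rate = rejections / n_replicates
    half = 2.5758293035489004 * np.sqrt(alpha * (1 - alpha) / n_replicates)
    return {"type1_rate": float(rate), "lower_99": float(alpha - half),
            "upper_99": float(alpha + half)}
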