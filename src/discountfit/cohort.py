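"""Synthetic cohorts of intertemporal-choice agents with known ground truth.

Agents choose between an immediate 20 EUR and delayed amounts via the
softmax rule under a known generating model, so every downstream stage
(ML fitting, model selection, BMS, Hessian diagnostics) can be validated
by parameter and model recovery.  Two task designs are emulated:

adaptive
    An adjusting-amount staircase per delay (delays 1, 2, 7, 14, 30, 90,
    180 days).  Following two successive choices of the delayed reward the
    delayed amount is reduced; following two successive immediate choices
    it is increased.  Delayed amounts are at least 20.5 EUR with no upper
    limit, and each delay's staircase terminates once the gap between the
    lowest accepted and highest rejected delayed amount reaches a
    delay-specific criterion (1.0, 1.5, 2.0, 2.0, 3.0, 4.0, 4.0 EUR).

fixed_offers
    A pre-computed offer set per delay (delays 0.25, 1, 7, 30, 90, 180
    days): from a prior hyperbolic discount-rate estimate k_hat, the
    predicted indifference amount A* = 20*(1 + k_hat*D) is clipped to
    [20.5, 80] and half the offers are drawn uniformly below A*, half
    above.

Generating-parameter populations are calibrated to published cohort
summaries (medians and inter-quartile ranges per model for two healthy
datasets and a pathological-gambler group): log-normal for rates and beta,
zero-truncated normal for exponents.

Seeding is hierarchical: master seed -> per-agent streams -> per-delay
substreams, so cohorts are bit-reproducible and agents are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .likelihood import TrialRecord, choice_probability
from .models import get_model, subjective_value

__all__ = [
    "AgentSpec",
    "CohortConfig",
    "AdaptiveSession",
    "StaircaseBlock",
    "ADAPTIVE_DELAYS",
    "ADAPTIVE_CRITERIA",
    "FIXED_DELAYS",
    "POPULATION_PRESETS",
    "population_preset",
    "simulate_choice",
    "run_adaptive_session",
    "generate_fixed_offer_set",
    "generate_cohort_dataset",
]

AMOUNT_SS = 20.0
MIN_LL_AMOUNT = 20.5
MAX_FIXED_AMOUNT = 80.0

ADAPTIVE_DELAYS = (1.0, 2.0, 7.0, 14.0, 30.0, 90.0, 180.0)
ADAPTIVE_CRITERIA = (1.0, 1.5, 2.0, 2.0, 3.0, 4.0, 4.0)
FIXED_DELAYS = (0.25, 1.0, 7.0, 30.0, 90.0, 180.0)

# Staircase mechanics (start amount / step schedule are free choices of the
# simulator; recovery must not hinge on them).
STAIRCASE_START = 50.0
STAIRCASE_STEP = 15.0
STAIRCASE_STEP_FLOOR = 0.25
MAX_TRIALS_PER_DELAY = 100

_Z75 = 0.6744897501960817  # 75th-percentile standard-normal quantile

# (median, q25, q75) of ML parameter estimates per model, for two healthy
# cohorts ("dataset1": fixed-offer fMRI datasets; "dataset2": adaptive
# task) and pathological gamblers.
POPULATION_PRESETS: Dict[str, Dict[str, Dict[str, Tuple[float, float, float]]]] = {
    "dataset1": {
        "H": {"beta": (2.16, 1.06, 2.88), "k": (0.0083, 0.0042, 0.0166)},
        "E": {"beta": (2.44, 1.16, 3.87), "k": (0.0055, 0.0032, 0.009)},
        "GM": {"beta": (1.36, 0.72, 1.93), "k": (0.0434, 0.0064, 0.0409),
               "s": (0.403, 0.174, 0.895)},
        "R": {"beta": (1.36, 0.65, 1.97), "k": (0.0366, 0.0068, 0.091),
              "s": (0.713, 0.429, 0.938)},
        "CS": {"beta": (1.22, 0.62, 1.94), "a": (0.0049, 0.0015, 0.0084),
               "b": (0.562, 0.348, 0.755)},
    },
    "dataset2": {
        "H": {"beta": (4.29, 2.59, 6.66), "k": (0.0112, 0.0047, 0.0249)},
        "E": {"beta": (6.59, 3.04, 10.99), "k": (0.0055, 0.0029, 0.0097)},
        "GM": {"beta": (2.56, 1.46, 3.51), "k": (0.0991, 0.0087, 0.4231),
               "s": (0.543, 0.159, 1.03)},
        "R": {"beta": (2.28, 1.38, 3.51), "k": (0.0573, 0.01, 0.117),
              "s": (0.751, 0.449, 1.03)},
        "CS": {"beta": (2.16, 1.31, 3.64), "a": (0.0067, 0.0028, 0.0162),
               "b": (0.511, 0.357, 0.779)},
    },
    "gamblers": {
        "H": {"beta": (2.66, 1.51, 4.41), "k": (0.0463, 0.0125, 0.144)},
        "E": {"beta": (3.32, 1.66, 5.18), "k": (0.0314, 0.0073, 0.102)},
        "GM": {"beta": (1.82, 1.09, 2.45), "k": (0.0778, 0.0047, 0.328),
               "s": (0.712, 0.26, 1.34)},
        "R": {"beta": (1.77, 1.02, 2.43), "k": (0.0749, 0.0097, 0.191),
              "s": (0.752, 0.467, 0.998)},
        "CS": {"beta": (1.86, 0.86, 2.69), "a": (0.0287, 0.0068, 0.0592),
               "b": (0.681, 0.411, 0.899)},
    },
}


@dataclass(frozen=True)
class AgentSpec:
    """Generating model and parameters of one simulated participant."""

    agent_id: str
    model_id: str
    discount_params: Tuple[float, ...]
    beta: float

    def __post_init__(self) -> None:
        spec = get_model(self.model_id)
        if len(self.discount_params) != spec.n_params:
            raise ValueError("discount_params length mismatch")
        if any(p <= 0 for p in self.discount_params) or self.beta <= 0:
            raise ValueError("agent parameters must be positive")


@dataclass
class StaircaseBlock:
    delay: float
    criterion: float
    trials: List[TrialRecord]
    bracket: Optional[Tuple[float, float]]  # (lowest accepted, highest rejected)
    terminated: bool


@dataclass
class AdaptiveSession:
    agent_id: str
    blocks: List[StaircaseBlock]

    @property
    def trials(self) -> List[TrialRecord]:
        return [t for b in self.blocks for t in b.trials]


@dataclass
class CohortConfig:
    """Recipe for a simulated cohort.

    ``model_mix`` maps generating-model ids to mixture weights (a single id
    is accepted as shorthand).  ``preset`` names the parameter-population
    calibration; ``beta_median`` optionally overrides the preset's softmax
    noise level (e.g. for low-noise model-recovery cohorts).
    """

    n_agents: int
    model_mix: Dict[str, float] | str = "CS"
    preset: str = "dataset2"
    task: str = "adaptive"
    delays: Optional[Sequence[float]] = None
    criteria: Optional[Sequence[float]] = None
    n_per_delay: int = 20
    beta_median: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.model_mix, str):
            self.model_mix = {self.model_mix: 1.0}
        if self.preset not in POPULATION_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.task not in ("adaptive", "fixed_offers"):
            raise ValueError(f"unknown task {self.task!r}")
        bad = [m for m in self.model_mix if m not in ("H", "E", "GM", "R", "CS")]
        if bad:
            raise ValueError(f"unknown model ids in mix: {bad}")
        if self.delays is None:
            self.delays = ADAPTIVE_DELAYS if self.task == "adaptive" \
                else FIXED_DELAYS
        if self.task == "adaptive" and self.criteria is None:
            if tuple(self.delays) != ADAPTIVE_DELAYS:
                raise ValueError("criteria required for non-default delays")
            self.criteria = ADAPTIVE_CRITERIA


def population_preset(model_id: str, preset: str = "dataset2",
                      beta_median: Optional[float] = None):
    """(median, q25, q75) triples per parameter for one generating model."""
    table = dict(POPULATION_PRESETS[preset][model_id])
    if beta_median is not None:
        m, q25, q75 = table["beta"]
        scale = beta_median / m
        table["beta"] = (beta_median, q25 * scale, q75 * scale)
    return table


def _draw_param(name: str, triple: Tuple[float, float, float],
                rng: np.random.Generator) -> float:
    med, q25, q75 = triple
    if name in ("s", "b"):
        # zero-truncated normal, sd from the IQR of a normal
        sd = (q75 - q25) / (2 * _Z75)
        while True:
            val = rng.normal(med, sd)
            if val > 0:
                return val
    mu = np.log(med)
    sigma = (np.log(q75) - np.log(q25)) / (2 * _Z75)
    return float(np.exp(rng.normal(mu, sigma)))


def _draw_agent(agent_id: str, model_id: str, preset: str,
                beta_median: Optional[float],
                rng: np.random.Generator) -> AgentSpec:
    spec = get_model(model_id)
    table = population_preset(model_id, preset, beta_median)
    disc = []
    for pname, (lo, hi) in zip(spec.param_names, spec.default_bounds):
        val = _draw_param(pname, table[pname], rng)
        disc.append(min(max(val, lo), hi))
    beta = _draw_param("beta", table["beta"], rng)
    return AgentSpec(agent_id, model_id, tuple(disc), beta)


def simulate_choice(agent: AgentSpec, amount_ll: float, delay_ll: float,
                    rng: np.random.Generator,
                    amount_ss: float = AMOUNT_SS) -> str:
    """One softmax (Bernoulli) choice between the immediate and delayed offer."""
    sv_ll = subjective_value(agent.model_id, agent.discount_params,
                             amount_ll, delay_ll)
    p_ll = choice_probability(amount_ss, sv_ll, agent.beta)
    return "LL" if rng.random() < p_ll else "SS"


def _run_staircase(agent: AgentSpec, delay: float, criterion: float,
                   rng: np.random.Generator,
                   max_trials: int = MAX_TRIALS_PER_DELAY) -> StaircaseBlock:
    """Adjusting-amount titration at one delay.

    Two successive delayed choices trigger a reduction of the delayed
    amount, two successive immediate choices an increase; the step halves
    at each direction reversal.  An amount counts as *accepted* when a
    two-delayed run completed at it and *rejected* when a two-immediate
    run did; the staircase terminates once the gap between the latest
    accepted and latest rejected amounts reaches the criterion, and that
    pair is the terminal bracket.
    """
    amount = STAIRCASE_START
    step = STAIRCASE_STEP
    accepted_level: Optional[float] = None
    rejected_level: Optional[float] = None
    run_choice: Optional[str] = None
    run_len = 0
    last_direction = 0  # -1 down (after LL pair), +1 up (after SS pair)
    trials: List[TrialRecord] = []
    terminated = False

    for _ in range(max_trials):
        choice = simulate_choice(agent, amount, delay, rng)
        trials.append(TrialRecord(agent.agent_id, AMOUNT_SS, amount,
                                  delay, choice))
        run_len = run_len + 1 if choice == run_choice else 1
        run_choice = choice
        if run_len < 2:
            continue
        if choice == "LL":
            accepted_level = amount
            direction = -1
        else:
            rejected_level = amount
            direction = +1
        if accepted_level is not None and rejected_level is not None \
                and accepted_level - rejected_level <= criterion:
            terminated = True
            break
        if last_direction != 0 and direction != last_direction:
            step = max(step / 2.0, STAIRCASE_STEP_FLOOR)
        amount = max(amount + direction * step, MIN_LL_AMOUNT)
        last_direction = direction
        run_choice, run_len = None, 0

    bracket = None
    if accepted_level is not None and rejected_level is not None:
        bracket = (accepted_level, rejected_level)
    return StaircaseBlock(delay=delay, criterion=criterion, trials=trials,
                          bracket=bracket, terminated=terminated)


def run_adaptive_session(agent: AgentSpec,
                         delays: Sequence[float] = ADAPTIVE_DELAYS,
                         criteria: Sequence[float] = ADAPTIVE_CRITERIA,
                         seed: int = 0) -> AdaptiveSession:
    """Run the adjusting-amount staircase at every delay for one agent.

    Each delay gets its own random substream; staircases that fail to
    terminate within the trial budget are flagged (terminated=False).
    """
    if len(delays) != len(criteria):
        raise ValueError("delays and criteria must align")
    streams = np.random.SeedSequence(seed).spawn(len(delays))
    blocks = [
        _run_staircase(agent, d, c, np.random.default_rng(ss))
        for d, c, ss in zip(delays, criteria, streams)
    ]
    return AdaptiveSession(agent_id=agent.agent_id, blocks=blocks)


def generate_fixed_offer_set(k_hat: float,
                             delays: Sequence[float] = FIXED_DELAYS,
                             n_per_delay: int = 20, seed: int = 0):
    """Pre-computed offers bracketing hyperbolically predicted indifference.

    Returns a list of (delay, amount, degenerate_flag) triples; the flag
    marks offers from an interval collapsed by clipping A* to [20.5, 80].
    """
    if k_hat <= 0:
        raise ValueError("k_hat must be positive")
    if n_per_delay < 2 or n_per_delay % 2:
        raise ValueError("n_per_delay must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    offers = []
    half = n_per_delay // 2
    for d in delays:
        a_star = AMOUNT_SS * (1.0 + k_hat * d)
        a_star = min(max(a_star, MIN_LL_AMOUNT), MAX_FIXED_AMOUNT)
        lo_degenerate = a_star <= MIN_LL_AMOUNT
        hi_degenerate = a_star >= MAX_FIXED_AMOUNT
        below = rng.uniform(MIN_LL_AMOUNT, a_star, size=half) \
            if not lo_degenerate else np.full(half, MIN_LL_AMOUNT)
        above = rng.uniform(a_star, MAX_FIXED_AMOUNT, size=half) \
            if not hi_degenerate else np.full(half, MAX_FIXED_AMOUNT)
        for amt in below:
            offers.append((float(d), float(amt), lo_degenerate))
        for amt in above:
            offers.append((float(d), float(amt), hi_degenerate))
    return offers


def _hyperbolic_khat(agent: AgentSpec) -> float:
    # stand-in for the prior adaptive-task estimate: the agent's own rate
    return agent.discount_params[0]


def generate_cohort_dataset(config: CohortConfig):
    """Draw agents, run the task, return (dataset, truth, sessions).

    ``dataset`` maps subject_id -> list of TrialRecord (what the analysis
    sees); ``truth`` is the hidden ground-truth parameter table and is
    emitted separately so it can never leak into fitting inputs;
    ``sessions`` holds AdaptiveSession objects (adaptive task only) for
    indifference-point extraction.
    """
    models = sorted(config.model_mix)
    weights = np.array([config.model_mix[m] for m in models], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("model mix weights must be non-negative, not all zero")
    weights = weights / weights.sum()

    master = np.random.SeedSequence(config.seed)
    agent_streams = master.spawn(config.n_agents)
    dataset: Dict[str, List[TrialRecord]] = {}
    sessions: Dict[str, AdaptiveSession] = {}
    truth_rows = []
    for i, ss in enumerate(agent_streams):
        agent_id = f"agent{i:03d}"
        rng = np.random.default_rng(ss)
        model_id = models[rng.choice(len(models), p=weights)]
        agent = _draw_agent(agent_id, model_id, config.preset,
                            config.beta_median, rng)
        if config.task == "adaptive":
            task_seed = int(rng.integers(2 ** 31))
            session = run_adaptive_session(agent, config.delays,
                                           config.criteria, seed=task_seed)
            dataset[agent_id] = session.trials
            sessions[agent_id] = session
        else:
            offer_seed = int(rng.integers(2 ** 31))
            offers = generate_fixed_offer_set(_hyperbolic_khat(agent),
                                              config.delays,
                                              config.n_per_delay,
                                              seed=offer_seed)
            trials = []
            for d, amt, _flag in offers:
                if amt <= AMOUNT_SS:
                    amt = MIN_LL_AMOUNT
                choice = simulate_choice(agent, amt, d, rng)
                trials.append(TrialRecord(agent_id, AMOUNT_SS, amt, d, choice))
            dataset[agent_id] = trials
        row = {"agent_id": agent_id, "model_id": agent.model_id,
               "beta": agent.beta}
        row.update(dict(zip(get_model(model_id).param_names,
                            agent.discount_params)))
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return dataset, truth, sessions
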