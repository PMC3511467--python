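"""Compare fitted discounting parameters between two simulated groups.

Simulates a 'control' cohort and a more impulsive 'gambler' cohort (both
hyperbolic, rate populations calibrated to the respective group summaries),
refits each subject, and tests the group difference in k with a pooled
two-sample t test on square-root transformed values plus a rank-sum test.
"""

import numpy as np

from discountfit import (CohortConfig, compare_parameter, fit_subject,
                         generate_cohort_dataset)


def fitted_rates(preset, n, seed):
    cfg = CohortConfig(n_agents=n, model_mix="H", preset=preset, seed=seed)
    dataset, truth, _ = generate_cohort_dataset(cfg)
    return np.array([fit_subject(dataset[a], "H", seed=seed + i)
                     .params.discount_params[0]
                     for i, a in enumerate(truth.agent_id)])


controls = fitted_rates("dataset1", 18, seed=1)
gamblers = fitted_rates("gamblers", 17, seed=2)
print(f"median fitted k: controls {np.median(controls):.4f}, "
      f"gamblers {np.median(gamblers):.4f}")

t_res, w_res = compare_parameter(controls, gamblers, parameter="k",
                                 transform="sqrt")
print(f"\npooled t test on sqrt(k): t({t_res.df:.0f}) = {t_res.statistic:.2f},"
      f" p = {t_res.p_value:.4f} (two-tailed)")
print(f"Wilcoxon rank-sum:        U = {w_res.statistic:.0f}, "
      f"p = {w_res.p_value:.4f}")
print("\na significant difference with gamblers' k larger reflects the")
print("steeper discounting built into the gambler parameter population.")
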