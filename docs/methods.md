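# Methods

## Choice model

Every trial is a binary choice between a fixed immediate reward (20 €,
delay 0) and a larger delayed reward (amount ≥ 20.5 €, delay in real-valued
days; sub-day delays such as 0.25 are supported and never coerced).
Under a discount model M with parameters θ, the probability of choosing
the delayed (LL) option is logistic in the subjective-value difference,

    P(LL) = 1 / (1 + exp(−(SV_LL − SV_SS) / β)).

β is implemented as a temperature (divisor): larger β flattens the sigmoid
and makes choices noisier, which matches how stochasticity is usually
indexed in this literature. The inverse-temperature (multiplier)
convention is available through `beta_convention="multiplier"` for
sensitivity analyses; fitted β values are reciprocal between conventions
but likelihoods and model ranks are unchanged. Choice probabilities are
clipped to [1e−12, 1 − 1e−12] before logging so perfectly consistent
subjects yield a large finite log-likelihood rather than −∞; the logistic
is evaluated with a sign-branched form that cannot overflow.

## Discount functions

The five models (H, E, GM, R, CS; see README for forms) share bounds
k, a ∈ [1e−8, 10] and s, b ∈ [0.01, 20], wide enough to cover empirical
interquartile ranges by an order of magnitude on each side while keeping
every likelihood evaluation finite; β is bounded in [1e−3, 100]. At D = 0
all models return A exactly — for CS with b < 1 the term (aD)^b is taken
at its limit 0, which `numpy.power` honours. Exact nesting identities
(GM and R at s = 1 reduce to H; CS at b = 1 with a = k reduces to E) hold
to machine precision and are enforced by tests.

## Maximum-likelihood estimation

Per subject and model, the summed log choice likelihood is maximised with
a derivative-free Nelder–Mead simplex on log-scale parameters, which makes
the positivity constraints implicit without penalty terms; inside the
objective, parameters are additionally clipped to their bounds, and final
estimates sitting on a bound are reported with `boundary_flags`.
Convergence tolerances are 1e−6 on objective and parameters with at most
5000 iterations per start. Because the likelihood surface is multimodal
for dual-parameter models, each fit restarts from 20 random points
(rates and β log-uniform on [1e−4, 1] and [0.1, 10]; exponents uniform on
[0.25, 2.5]) and keeps the best; starts are drawn sequentially so that the
best-of-n likelihood is monotone in n. Cohort fitting derives per-subject
seeds from a master seed via `numpy.random.SeedSequence`, making tables
bit-reproducible; per-subject failures are returned as flagged rows, never
aborting the cohort.

Subjects whose choices are all identical produce a likelihood plateau
(any sufficiently extreme rate fits perfectly), so such fits are flagged
`degenerate_choices` rather than trusted; subjects with fewer than 10
trials are flagged `low_trials`.

AIC and BIC count β as a free parameter — n = 2 for H/E, n = 3 for
GM/R/CS. The alternative (excluding β everywhere) shifts all models'
scores equally and leaves every Δ comparison unchanged; counting it keeps
the penalty faithful to what is actually estimated.

## Model comparison

ΔAIC is computed per subject (row minimum subtracted) and at the group
level on column-summed scores — not by summing per-subject deltas, which
is a different quantity. Per-subject winners are the score argmin; exact
ties are resolved toward fewer free parameters, then the fixed order
H < E < GM < R < CS, a deterministic parsimony-consistent rule. Pairwise
model contrasts use two-sided Wilcoxon signed-rank tests on per-subject
deltas (the same subjects are scored under every model; delta
distributions are strongly skewed): zero differences dropped, exact null
for n ≤ 25 without ties, continuity-corrected normal approximation
otherwise. Uncorrected p-values are reported by default with an optional
Holm step-down; an independent-samples rank-sum variant is available for
comparison.

## Random-effects Bayesian model selection

Per-subject log model evidences are approximated as −AIC/2 (or −BIC/2).
The population frequency vector r follows a Dirichlet prior (α₀ = 1 per
model); the variational posterior iterates responsibilities
u_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα)) and concentrations α = α₀ + Σ_n u_n
until max|Δα| < 1e−4 (≤ 500 iterations). Evidences are mean-centred within
subject before exponentiation — the posterior is invariant to per-subject
constants, so this is purely a numerical-stability measure. Each subject
contributes at most one unit of responsibility, bounding outlier
influence. Exceedance probabilities P(r_k > r_j ∀ j) are estimated by
seeded Monte-Carlo Dirichlet sampling (10⁶ draws by default; the binomial
standard error is ≤ 5×10⁻⁴), except for two-model problems where the
closed form 1 − I₀.₅(α₁, α₂) is used automatically. Exceedance above 0.95
is flagged decisive.

## Identifiability diagnostics

The Hessian of the negative log-likelihood at the ML estimate is built by
central finite differences with absolute step 1e−3 on natural-scale
parameters (relative stepping is available); it includes β, so the matrix
is full 2×2 or 3×3, and cohort summaries slice out the rate–exponent
entry. The inverse Hessian is the asymptotic covariance; it is accepted
only if the Hessian passes a Cholesky factorisation, has condition number
below 1e8, and yields positive variances — otherwise the subject is
counted non-invertible and excluded from the average, mirroring how
boundary or ridge/plateau estimates are bookkept. Because the CS
impatience parameter a is typically ~0.005–0.03, an absolute 1e−3 step is
a large relative perturbation near zero; refitting with the optimiser
variable 100·a (the model evaluates a′/100) restores conditioning without
changing the correlation structure (correlations are scale-invariant),
and the rescaled run re-reports the non-invertible counts.

## Indifference-point analysis

The adjusting-amount staircase at each delay starts the delayed amount at
50 €, adjusts it after two successive same-direction choices (down after
two delayed choices, up after two immediate choices) by a step starting at
15 € that halves at each direction reversal (floor 0.25 €), keeps amounts
≥ 20.5 € with no upper limit, and terminates when the gap between the
latest accepted and latest rejected adjustment levels reaches the delay's
criterion (1.0, 1.5, 2.0, 2.0, 3.0, 4.0, 4.0 € at delays 1, 2, 7, 14, 30,
90, 180 days). The start amount and step schedule are free choices of the
simulator — the original task reports neither — and recovery results
should not (and in tests do not) hinge on them. Terminal-bracket midpoints
define indifference amounts; for a deterministic agent the bracket
straddles the true indifference point, so the midpoint is within half the
criterion of truth. Staircases that fail to terminate within 100 trials
per delay are flagged and yield missing points.

Curve fits use discount fractions (20 €/indifference amount ∈ (0, 1]), so
the amount drops out and the fitted curve is SV(A=1, D); fitting uses
multi-start bounded least squares on log-scale parameters, and
R² = 1 − SS_res/SS_tot about the mean fraction is reported as computed
(negative values are not clipped). Group aggregation takes per-delay
medians (mean of central pair for even counts) and refuses mixed delay
grids — cohorts with six- and seven-point subsets must be aggregated per
subgroup.

## Synthetic cohorts

Agents' generating parameters are drawn from populations calibrated to
published cohort summaries (medians and IQRs per model for two healthy
datasets and a pathological-gambler group): log-normal for rates and β
(μ = ln median, σ = IQR width of the log values over 2·Φ⁻¹(0.75)),
zero-truncated normal for exponents. Under these defaults an adaptive
session yields roughly 90–155 trials per agent (median ≈ 110). The
fixed-offer design pre-computes, from a hyperbolic rate estimate, the
predicted indifference amount A* = 20·(1 + k̂·D) clipped to [20.5, 80] €
and draws half the offers uniformly below and half above A*; collapsed
intervals after clipping are flagged. In simulation the agent's own rate
parameter stands in for the prior-task estimate k̂. Seeding is
hierarchical (master → agent → delay), and ground-truth tables are emitted
separately from trial tables so truth cannot leak into fitting inputs.

What the generator does *not* emulate: session effects, attention lapses
or trembling-hand errors, within-subject parameter drift, magnitude
effects (the immediate amount is always 20 €), and real offer-scheduling
idiosyncrasies. Passing recovery tests therefore show that the estimation
and selection machinery is correct and well-calibrated under the assumed
choice model at realistic trial counts and noise levels — not that real
participants satisfy those assumptions.

## Group and condition statistics

Parametric comparisons run on square-root transformed parameters — unlike
the log transform, √ keeps the lower bound at 0 and tolerates estimates
approaching zero — using a pooled-variance two-tailed t test
(df = n₁ + n₂ − 2; Welch optional) or its paired analogue; the matching
Wilcoxon rank-sum or signed-rank test is always reported alongside on raw
values (ranks are transform-invariant). Scaling exponents are tested
against 1 with one-sample signed-rank tests on exponent − 1. Under the
null the sqrt-t test's empirical type-I error is calibrated to ≈5%
(verified over 1000 simulated replicates).

## Validation studies and problem sizes

`discountfit.recovery` packages the validation suite used by the tests
and the acceptance script: nesting identities on a 10⁴-point (A, D) grid;
optimizer-vs-40³-lattice likelihood gaps on three 30-trial toy subjects;
MC-vs-closed-form exceedance on ten random two-model problems at 10⁶
samples; parameter recovery with 50 agents per generating model
(expect rate rank-correlation ≥ 0.8 and β within ×2 for ≥ 80%); model
recovery on five replicates of 40-agent low-noise CS cohorts (β median
0.5; expect decisive CS exceedance in ≥ 4/5); the Hessian correlation
contrast on 20-agent cohorts per dual-parameter model; the R²–rate
confound across 100 hyperbolic subjects with log-uniform k on
[0.003, 0.1] and β = 2; and type-I calibration over 1000 null replicates
at group sizes 17/18. These sizes are the package's chosen defaults for a
single-workstation run and are passed explicitly everywhere, so larger
replications are one keyword away.

## Known limitations

- Log evidence is approximated by −AIC/2; a full Laplace or hierarchical
  evidence would weight parameter uncertainty differently.
- The Hessian-based covariance is asymptotic and local; profile-likelihood
  or bootstrap intervals are out of scope.
- No lapse-rate/tremble mixture in the choice rule: a few random choices
  from an otherwise deterministic subject inflate β rather than a lapse
  parameter.
- GM's rate recovery is the weakest of the five (rank correlation near
  the 0.8 mark) — an expected consequence of its strong k–s likelihood
  ridge, which is precisely the identifiability problem the Hessian
  diagnostics quantify.
- Staircase mechanics (start amount, step schedule) are assumptions;
  indifference estimators other than the terminal-bracket midpoint are
  not implemented.
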