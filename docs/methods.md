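# Methods

## Design overview

`cohortcal` implements a new-user, active-comparator comparative cohort
analysis with four pre-specified validity diagnostics and negative-control
empirical calibration. The causal contrast is a hazard ratio for a
time-to-first-event outcome, estimated among propensity-matched initiators
of a target versus a comparator therapy, so the estimand is an average
treatment effect in the region of propensity overlap. The package's core
commitment is *fail-closed reporting*: an effect estimate is withheld
(blinded, rendered NA) unless every diagnostic passes, because a
confounded or inestimable result is worse than no result.

## Synthetic data generator

The generator (`synthetic_data`) emulates one observational database at
the level of abstraction the analysis consumes, with known ground truth:

- **Covariates.** `n_covariates` independent binary covariates with
  prevalences drawn log-uniformly over `covariate_prevalence_range`
  (default 0.001–0.3). Log-uniform sampling concentrates mass at low
  prevalence, mimicking the long tail of diagnosis/drug/procedure codes
  in claims data. Defaults (2,000 covariates, 40,000 persons in two
  20,000-person cohorts) describe a mid-sized database.
- **Confounding.** The first `n_confounders` covariates carry non-zero
  coefficients in both the treatment model (logistic, log-odds
  `treatment_coefs`, default alternating ±0.7) and the outcome hazards
  (log-hazard `outcome_coefs`, default alternating ±0.5). The treatment
  intercept is solved by root finding so the expected treated count
  equals `n_target`.
- **Outcomes.** Constant-hazard (exponential) event times — the simplest
  model satisfying proportional hazards, which is all the Cox analysis
  assumes. The outcome of interest has baseline hazard `baseline_hazard`
  (default 1e-4/day, an uncommon event) and treatment effect
  `true_log_hr`. Each of `n_negative_controls` (default 86) control
  outcomes draws its own baseline hazard (log-uniform over
  `nc_baseline_hazard_range`) and a true log-HR
  $b_k \sim N(\mu_{bias}, \sigma_{bias}^2)$; setting $\sigma_{bias} > 0$
  injects residual systematic error that the calibration machinery should
  detect. Events are recorded on day $\lceil t \rceil$ after index.
- **Exposure eras.** Administrations start on the index day and repeat
  every `admin_interval_days` (default 56, an 8-week maintenance
  schedule) with geometric per-cycle dropout
  (`persistence_dropout_prob`, default 0.15). Censoring-drug exposures
  arrive as a rare memoryless process (`censor_exposure_rate`, default
  2e-4/day) so the on-treatment right-censoring logic is exercised; no
  published rate exists for this, so it is a package choice.
- **Pre-index events.** With probability `prior_outcome_prob` (default
  0.002) a person carries a pre-index occurrence of an outcome, so the
  prior-event exclusion has work to do.
- **Determinism.** A single seed is split into named sub-streams
  (covariates, treatment, observation, administrations, censoring,
  outcome, negative controls), so identical configs give byte-identical
  studies and changing the number of controls does not perturb cohort
  composition.

What the generator does *not* emulate: covariate correlation structure,
time-varying confounding, differential outcome capture between claims and
EHR sources, and code-vocabulary semantics. Passing tests therefore
demonstrate the statistical machinery's operating characteristics under
its stated assumptions, not performance on any real database.

## Time at risk and design restrictions

TAR intervals are inclusive integer-day intervals; `days_at_risk =
end − start + 1` and an event on the end day counts. The on-treatment TAR
runs from the day after index through the era of persistent exposure
(successive administrations ≤ 90 days apart) plus 90 days of
surveillance, capped at observation end and right-censored *on* the first
censoring-drug exposure day. The ITT TAR runs to observation end and is
never right-censored. Design restrictions apply sequentially — calendar
overlap of the two arms' index ranges (implemented as index-range
intersection, since no exact published rule exists), exclusion of
pre-index outcomes (`event_day ≤ index_day`), exclusion of zero days at
risk — and each step's attrition is recorded. Person-years use a
365.25-day year.

## Propensity model

The LSPS is an L1-regularized logistic regression on all covariates
(scikit-learn, liblinear). A Laplace prior with variance $v$ maps to the
L1 penalty $\lambda = \sqrt{2/v}$. The prior variance is selected from
the log-spaced grid {0.001, 0.01, 0.1, 1, 10} (anchored at the
conventional 0.01 starting value) by 10-fold stratified CV maximizing
out-of-fold log-likelihood; fold fits use a looser tolerance (1e-5) than
the final fit (2e-7) purely as a numerical economy. The intercept is
effectively unpenalized (`intercept_scaling=10`). Scores are in-sample
predicted probabilities clipped to (1e-10, 1−1e-10) with a warning on
boundary scores (separation). Equipoise is computed on the pooled
pre-matching analytic population, matching its role as a feasibility
diagnostic applied before any balancing.

## Matching

Greedy variable-ratio caliper matching on the logit-PS, caliper 0.2 ×
SD(logit PS) pooled over both arms. The algorithm runs `ratio_cap`
rounds; each round, targets — visited in a seeded shuffled order fixed
across rounds — claim their nearest still-unmatched comparator within the
caliper. Targets with no match after round 1 are excluded. Distance ties
break toward the lower input ordinal; these two rules (order, tie-break)
are package choices required for determinism, since "greedy" alone does
not pin down an order. 1:1 matching is the same algorithm with
`ratio_cap=1`. Balance (ASD before/after) is computed for *every*
covariate, not only those in the final PS model. Nearest-available
lookups use a doubly-linked list over score-sorted comparators, so
matching is near-linear in cohort size.

## Stratified Cox estimation

With a single 0/1 covariate the matched-set-stratified partial likelihood
has closed-form score and information in terms of per-(stratum ×
event-day) risk-set counts, so the package solves it with a scalar Newton
iteration over vectorized count arrays; it reproduces lifelines'
`CoxPHFitter(strata=...)` to ~1e-10 while scaling to the tens of
thousands of strata × 87 outcomes the simulations need. Efron tie
handling is the default (day-granularity data guarantees ties; Breslow
is available for comparison). Strata with no event or no treatment
contrast drop out of the likelihood, as in any conditional analysis. A
likelihood with all informative events in one arm is monotone; the fit
warns and flags non-convergence rather than failing. The minimum
detectable relative risk uses the standard two-sided Wald power formula
$\exp\!\big((z_{1-\alpha/2}+z_{power})/\sqrt{E f (1-f)}\big)$ with $E$
total events and $f$ the treated fraction of person-time.

## Empirical null, EASE, calibration

Negative-control estimates reuse the outcome-independent matched sets;
each control applies its own pre-index exclusion and non-zero-events
gate, and gated-out controls are recorded as inestimable and excluded
from the null fit. The null $(\mu, \sigma)$ maximizes the likelihood of
$\hat\beta_i \sim N(\mu, \sigma^2 + \hat\tau_i^2)$; the optimizer works
on $(\mu, \log\sigma)$ (smooth at the $\sigma \to 0$ boundary) and the
result is compared against the exact $\sigma = 0$ profile solution,
taking whichever attains the lower negative log-likelihood. EASE is the
folded-normal mean, with the degenerate limit $|\mu|$ at $\sigma = 0$.
Calibration treats systematic error as additive and constant on the
log-HR scale: $\hat\beta_{cal} = \hat\beta - \mu$,
$se_{cal} = \sqrt{se^2 + \sigma^2}$. Richer calibration models let the
systematic error scale with the estimate's SE; the constant-error
convolution is a deliberate simplification and the natural toggle point
for extending the package. All intervals use $z = 1.959964$ (asymptotic
Wald, not t).

## Diagnostics and synthesis

The four gates and their boundary conventions, fixed a priori: events
> 0 in both arms; max ASD < 0.1 strictly (an ASD of exactly 0.1 fails);
equipoise proportion ≥ 0.35 (exactly 0.35 passes); EASE ≤ 0.25 (exactly
0.25 passes). DerSimonian–Laird pooling uses the moment estimator
$\tau^2 = \max(0, (Q-(k-1))/(\sum w_i - \sum w_i^2/\sum w_i))$ and pools
calibrated log-HRs only when $I^2 < 0.40$ strictly and at least two
databases pass all diagnostics. Small-cell masking (rendering counts 1–4
as "<5") is a report-rendering option only and never touches internal
computation. The results table is written as CSV with a JSON summary;
no HTML report is produced — interactive exploration is out of scope.

## Phenotype evaluation

Confusion-matrix cells are sums of model-assigned case probabilities
(real-valued TP/FP/FN/TN), which reduces exactly to the deterministic
matrix when probabilities are 0/1. Metrics are always computed from the
unrounded sums; counts shown in reports are rounded for display. This is
why published tables built the same way can contain metric values that do
not exactly recompute from their printed integer counts — the package
reproduces the metric, not the rounding. Undefined ratios (zero
denominators) are returned as NaN rather than raised.

## Simulation scale and numerical choices

The operating-characteristic simulations in the test suite run the full
pipeline at 4,000 persons per arm with 500 covariates (20 confounders,
86 negative controls, 20 replicates per scenario) — the package's chosen
simulation scale; coverage of a 95% interval and the EASE gate's response
to injected bias are scale-free properties, while absolute precision of
any single estimate is not. Replicate seeds derive from one fixed
seed-sequence stream. Noteworthy finite properties observed at this
scale and documented rather than hidden: with strong shared confounding
the matched estimate retains a small residual bias that the negative
controls only partially absorb (they share the confounding structure but
also their own sampling noise), and with $\sigma_{bias}$ chosen so the
true EASE sits just above the 0.25 threshold, the gate's per-replicate
failure probability is materially below 1 because $\hat\sigma$ has
sampling spread $\approx \sigma_{bias}/\sqrt{2K}$ with $K = 86$ controls.

## Known limitations

- Covariates are generated independently; real claims covariates are
  strongly correlated, which stresses L1 selection differently.
- The calibration model assumes exchangeable, normally distributed
  systematic error across outcomes.
- No proportionality testing, no covariate-adjusted (beyond
  stratification) Cox models, no weighting estimators (IPTW, fine
  stratification) — matching is the only adjustment strategy.
- Negative controls are generated, not selected; the real-world problem
  of *choosing* valid negative controls is out of scope.
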