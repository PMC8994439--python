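# Methods

This note documents the model implemented in `hystcea`: its structure,
parameter handling, numerical conventions, the synthetic-data generator used
for verification, and known limitations. Everything quantitative below is
computed by the package's tests or scripts; nothing is asserted from memory.

## Decision model

A patient undergoing hysterectomy for a presumed benign indication passes
through: surgical route (TAH, SAH, VH, TLH, LSH) drawn from the scenario's
route mix; uncontained power morcellation with a route-specific proportion
(laparoscopic routes only; zero in the postwarning scenario); a
perioperative outcome (death, major complication, minor complication, none)
with route-specific probabilities; occult-cancer status (endometrial
carcinoma or uterine sarcoma) with age-group-specific prevalence; and a
monthly survival process to age 100.

Branch conventions:

- Perioperative deaths exit the tree before cancer evaluation: a patient who
  dies in hospital contributes no cancer pathway and no morcellated-cancer
  count. (At death probabilities of 1–2 per 10,000 this changes counts by
  ~0.01%.)
- Occult-cancer prevalence depends on age only — not on route or
  morcellation status.
- Morcellation affects outcomes only through the cancer subtree (survival of
  occult disease), matching the scope of the safety warning.

## Survival

Occult-cancer strata follow Weibull accelerated-failure-time survival
S(t) = exp(−(t/λ)^k), λ = exp(η), with
η = θ_morc for morcellated disease and η = θ_morc + θ_sc or θ_morc + θ_tot
for non-morcellated supracervical/total hysterectomy. The "scale factor" is
interpreted as the log-scale linear predictor (λ = exp(η)); this yields
clinically plausible medians (e.g. ≈59 months for morcellated sarcoma with
η = 4.41, k = 1.12) and is the parameterization recovered by the estimation
stage. Extent covariates: SAH and LSH map to "supracervical"; TAH, TLH and
the vaginal route to "total" (anatomical correspondence; the source of this
assignment for vaginal-route patients is not documented and is a package
choice).

Other-cause mortality uses an annual life table converted to monthly
probabilities via 1 − (1 − q)^(1/12) at the attained integer age. Within a
monthly cycle the cancer hazard applies first; other-cause deaths that month
are drawn from patients who did not die of cancer. Anyone alive at age 100
is absorbed as an other-cause death. A patient alive at the start of a month
accrues that month's full cost and utility (no half-cycle correction); the
expectation and microsimulation engines share this convention and the same
per-pathway value arrays, so they agree in expectation (verified within
3 Monte Carlo standard errors at N = 200,000).

**Life table.** The cited female period life table is not printed in the
source material, so the package ships a synthetic stand-in
(`lifetable_female_synthetic.csv`): a Gompertz–Makeham curve
q(x) = 2.4·10⁻⁴ + 2.6·10⁻⁵·e^{0.095x}, calibrated to published summary
levels of U.S. female mortality around 2015 (q ≈ 4·10⁻⁴ at 20, ≈ 8·10⁻³ at
60, ≈ 0.05 at 80), with q(100) forced to 1. All-cause mortality approximates
"death from causes other than uterine cancer"; uterine cancer is a small
share of female mortality, so the approximation is mild.

## Costs, utilities, discounting

- Surgery episode costs are route-specific; death/major/minor add
  incremental costs. Productivity loss = weekly earnings × route-class
  recovery time (5 weeks abdominal, 3 weeks vaginal/laparoscopic), applied
  below age 65 and not for in-hospital deaths.
- Recovery-window utilities: the route utility applies over the recovery
  window (weeks × 12/52 months, blended linearly into full health within a
  fractional month); a complication replaces the first month with the
  complication utility. Cancer-free survivors then accrue utility 1.0 until
  death. The published inputs give utilities and recovery durations but not
  application windows; these windows are package choices, configurable via
  the parameter table.
- Occult-cancer patients accrue the cancer phase schedule from the month
  after surgery (diagnosis at surgery): initial phase = first 12 months,
  end-of-life phase = last 12 months before death (taking precedence when
  death occurs within 24 months of diagnosis), continuing phase between.
  End-of-life rates and utilities differ by cause of death (uterine cancer
  vs other causes). Monthly cancer costs switch from the <65 to the ≥65
  schedule at the attained-age month, not the age at surgery. The
  cancer-phase utility supersedes the recovery-window utilities for these
  patients.
- Discounting: 3%/year as monthly factors (1.03)^(−t/12) from month 1;
  the surgical episode itself is undiscounted (month 0).

## Parameters and probabilistic sensitivity analysis

Every input lives in a CSV registry (id, base, low, high, family, units).
Families: `point` (never perturbed), `normal` (sd = (high−low)/3.92,
truncated to the quantity's domain — probabilities and utilities to [0,1],
shapes to >0), `lognormal` (log-scale mean/sd moment-matched to the printed
CI endpoints, so draw percentiles reproduce the CI; rows whose printed
interval is a min–max range, e.g. recovery weeks, are treated the same way
since they are declared lognormal), and `beta` (rescaled to [low, high] with
the mode at the base value and fixed concentration α+β = 10, since only base
and range are published). `derived` rows are recomputed after every draw:
the counterfactual TAH share as 1 − (SAH+VH+TLH+LSH) (floored at zero and
renormalized jointly — the published analysis does not state how
sum-to-one was preserved), the vaginal-route aliases, and end-of-life
schedules that reuse continuing-phase values. The printed postwarning route
percentages sum to 99.99% and are rescaled to an exact probability vector.
All parameters are drawn independently (any correlation structure in the
original PSA is unpublished).

PSA: 1,000 iterations by default; each iteration draws one parameter set
applied to *both* scenarios (common random parameters — required for
meaningful increments), evaluates both in exact-expectation mode, and
records ΔC, ΔQ and every drawn value. CEAC: fraction of iterations with
incremental net monetary benefit λ·ΔQ − ΔC ≥ 0 (ties cost-effective) on a
$0–$250k grid. Influence ranking uses Spearman rank correlation between
each varying parameter and the INMB at λ = $50,000/QALY (the original
ranking method is unpublished supplementary material; partial rank
correlation is available as an option). Constant parameters are excluded.

## Age distribution

The published postwarning age distribution has five bins; prevalence needs
eleven groups. Disaggregation: uniform 50:50 within ten-year bins, 18–34
split 50:50 into 18–29/30–34, and 65+ split 40:30:30 into 65–69/70–74/75+.
The split weights are configurable; the morcellated-sarcoma count is the
quantity most sensitive to this choice (sarcoma prevalence is non-monotone
in age). Each group is represented in the Markov process by a midpoint age
(24, 32, 37, 42, 47, 52, 57, 62, 67, 72, 80).

## Estimation stages

- Route model: maximum-likelihood multinomial logit (reference TAH) on age
  and the indication/comorbidity/procedure covariates; fitted with Newton
  iterations (a vanishing score is accepted when the iteration limit is hit
  while oscillating at the optimum).
- Counterfactual standardization: the prewarning route model's predicted
  probabilities averaged over the postwarning sample. CIs by percentile
  bootstrap over records with coefficients held fixed (200 resamples,
  seeded); refitting the multinomial model per resample is not attempted,
  and the original CI method is unpublished.
- Outcome model: multinomial logit of major/minor/none on route dummies and
  covariates, in-hospital deaths excluded; "mean characteristics" is the
  covariate-mean plug-in (one prediction at fractional means), with
  record-averaged prediction available as an option.
- Cost model: gamma GLM with log link on route, outcome indicators and
  covariates; incremental event costs are the multiplicative coefficients
  converted to dollars at the mean-covariate baseline.
- Survival: `lifelines` Weibull AFT per histology with the two
  non-morcellation stratum indicators; right-censoring in the likelihood;
  an all-censored sample raises, an all-censored stratum is flagged.

Verification is by parameter recovery on the synthetic generator: over 20
seeded replicates at n = 50,000 (5,000 for survival), 95% CI coverage of
the generator truth is approximately nominal (asserted ≥ 90% pooled), and
the standardization identity (mean fitted probabilities = observed shares)
holds to optimizer tolerance.

## Synthetic cohorts

The generator emulates the restricted administrative inputs: covariates
drawn independently given age group from marginal frequencies approximating
the postwarning sample; route from a known multinomial logit whose
intercepts target the prewarning mix; outcome from per-route death
probabilities plus a known logit whose implied risks mirror the published
per-route complication risks; cost from a gamma model whose constants mirror
the published per-route episode costs; follow-up times from the published
Weibull parameters under uniform administrative censoring over a
configurable window. What passing recovery tests show: the estimation code
correctly inverts these generative forms at realistic sample sizes. What
they do not show: robustness to covariate correlation, model
misspecification, coding error in real claims data, or informative
censoring — none of which the generator emulates (a hook exists for
injecting correlations).

## Problem sizes and runtime choices

Scenario evaluation is exact expectation over branches with O(months)
per-pathway value arrays (prefix sums over the phase schedules), so a full
base case runs in tens of milliseconds and a 1,000-iteration PSA in well
under a minute. The test suite uses 50,000-record cohorts for regression
recovery, 5,000 for survival recovery, N = 200,000 for the
expectation-vs-microsimulation comparison, 1,000 random parameter sets for
tree-conservation checks, and a 300-iteration PSA for acceptability-curve
properties — sizes chosen so the full suite completes in about a minute
while keeping Monte Carlo error well below the tested tolerances.

## Known limitations

- The expected total QALYs/costs (and hence the exact ICER) depend on
  unpublished details — utility application windows, the fine age
  distribution, life-table values, and the mortality-assignment rule for
  perioperative deaths — so the package reproduces the published
  complication and morcellated-carcinoma counts closely (within 0.5% and
  ~2% respectively) but matches the published QALY/cost increments only in
  direction and magnitude, not to the printed digit.
- No contained- or manual-morcellation arms; no payer or hospital
  stratification; cancer-free survivors accrue utility 1.0 rather than
  age-specific population norms.
- Prevalence, route mix and Weibull draws are sampled independently in the
  PSA.
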