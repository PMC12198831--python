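# Methods

This note records the model, its assumptions, the defaults and why they
were chosen, and what the tests do and do not demonstrate.

## Population synthesis

A cohort is specified entirely by aggregate data: one quantile grid per
variable (age; sex as a binary; FIT in µg Hb/g faeces; blood-count analytes
in clinical units) and a correlation matrix on a latent Gaussian scale.
Sampling is a Gaussian copula: draw z ~ MVN(0, R) through the symmetric
eigendecomposition square root (so positive-*semi*definite matrices are
accepted), map each column through Φ to a uniform rank, and refit the rank
onto the variable's grid by linear interpolation between grid points,
clipping to the configured bounds beyond the outermost points. Sex uses a
latent threshold on its uniform, keeping one sampling mechanism for all
covariates. Because ranks are invariant under monotone transforms, the
`transform` field of a marginal documents the scale of the aggregate inputs
rather than changing the sampler. Ages are truncated to [18, 100] — an
adult symptomatic population with the lifetime-model age cap — and
generated continuous; the annual-cycle engine floors them to whole years.

The refit operation (`apply_quantile_refit`) treats inputs inside [0, 1] as
cumulative ranks and anything else as raw values to be ranked first with
plotting positions (r − ½)/n; either way it is a monotone rank-preserving
remap, so grid probabilities map exactly onto grid values.

**Stand-ins.** The real aggregate grids and correlations are not public.
The shipped validation-style defaults were chosen once for clinical
plausibility: median age 58, 45% male, a heavily right-skewed FIT with 20%
of the cohort at or above the 10 µg/g referral threshold (so refer-all vs
FIT-10 referral volumes per million have the right order of magnitude),
haemoglobin and MCV with anaemia negatively correlated with FIT, and a 91%
recent-blood-count share. The derivation-style cohort is slightly older
with a heavier FIT tail. A user supplies real aggregates as YAML via
`crctriage.io`.

## Risk models and calibration

Both model forms are data: coefficient maps with per-covariate transforms
(identity or log1p), plus a 1-year baseline survival S₀ (Cox) or intercept
(logistic). The shipped coefficients are labelled synthetic stand-ins
(positive age, male and log-FIT effects; negative haemoglobin and MCV
effects), which is enough to reproduce the qualitative behaviour that
matters: at matched CRC detection the score refers fewer people than a
FIT-only threshold, reorienting referrals from low-yield young patients
towards high-yield older ones.

Because stand-in coefficients carry no absolute calibration, the pipeline
calibrates at run time on each generated cohort: S₀ (or the intercept) is
solved with Brent's method so the cohort mean 1-year risk equals the target
incidence — 1.2% for the validation-style cohort, 1.5% for the
derivation-style one. CRC is then allocated as an independent Bernoulli at
each person's risk, so baseline prevalence matches the target up to
binomial noise. `prevalence_scaling` in the disease configuration remains
at 1 and exists only for user-supplied models that should not be
recalibrated.

## Disease allocation

CRC stage at baseline is drawn from a configurable distribution (default
25/30/30/15% across I–IV, illustrative). Among CRC-free persons, high-risk
adenomas are assigned within each FIT stratum (≥10 / <10 µg/g; defaults 8%
and 1.5%) with probability proportional to the risk score normalised to the
stratum mean — the score is assumed to have some sensitivity for high-risk
adenomas without a published formula, so proportional weighting is the
simplest monotone choice. Low-risk adenomas are uniform (10%). IBD is an
independent flag from a decade-of-age × FIT-stratum table, young- and
high-FIT-skewed. CRC, adenoma and normal epithelium are mutually exclusive;
IBD can coexist with any of them.

## Short-term pathway

Everyone accrues a GP appointment and a FIT. Risk-score strategies add
£0.01/person for running the algorithm and £8.38 for phlebotomy plus
haematology in patients without a recent blood count; a scenario charges
everyone. Referred patients attend with probability `uptake` (default
0.95); 15% of attenders get CT colonography, the rest colonoscopy, each
with per-condition sensitivities. Detected CRC has zero diagnostic delay.
Missed or unreferred CRC draws a personalised delay from a lognormal
truncated to [2 weeks, 2 years] with σ(log) = 0.8 fixed and location solved
numerically so the truncated mean is 3 months (6 in the doubled-delay
scenario); the delay's costs — the definitive investigation at delayed
diagnosis (an assumption: the source is silent on whether it is charged),
two extra GP appointments, and an emergency presentation in 20% of delayed
cases — are discounted by the personal delay. IBD missed at referral waits
a fixed 1.34 years. Colonoscopy carries an expected complication cost and
QALY decrement (probability × decrement); the harm scenario replaces the
decrement with exactly one day of full health, 1/365.25 QALY, per
procedure.

Strategies are compared with common random numbers: each person owns a
fixed vector of uniforms (uptake, CTC assignment, per-condition detection,
delay, emergency) drawn once per cohort, so a person whose referral status
agrees under two strategies has bit-identical outcomes under both and
incrementals are paired.

## Lifetime model

Expected-value (fractional occupancy) per-person traces with annual cycles
to age 100, accrual at cycle start, no half-cycle correction, year-0
accruals undiscounted, discounting by ⌊years⌋ at 3.5% (1.5%/5% scenarios).
Disease-free persons are resolved once per (age, sex) cell.

A CRC case's stage distribution at diagnosis is the baseline stage exposed
to the continuous-time chain I→II→III→IV for the length of its delay, with
rates λ = −ln(1−p) from the annual progression probabilities (defaults
0.35/0.40/0.45; the fast-transition scenario uses stand-in upper bounds
0.70/0.75/0.80). The matrix exponential is evaluated through the
eigendecomposition of the generator, vectorised over persons, with a scipy
`expm` fallback for near-degenerate rates.

**Design choice — where the diagnosed trace starts.** The diagnosed trace
starts at baseline with the stage distribution reached by the *end* of the
delay, rather than pausing in an undiagnosed state until the next cycle
boundary. Pausing would hand delayed cases a full healthy-utility,
CRC-mortality-free cycle — delay would postpone the entire survival curve
and look beneficial. Starting the diagnosed course at baseline makes the
harm of delay exactly its stage shift, strictly monotone in delay, at the
cost of charging first-year treatment slightly early (delays are at most
two years). After diagnosis the stage is fixed; annual CRC death
probability is looked up by (stage, sex, age band, years since diagnosis
1–10, later years reusing the year-10 row), applied before other-cause
life-table mortality. Utilities are general-population (age band × sex)
times a stage/phase multiplier; costs are annual by stage and phase
(first year vs subsequent) plus a terminal cost in the cycle of CRC death.

IBD consequences are inert unless the relevant scenario is on: then
USC-detected cases carry the routine annual cost/utility stream and
delayed cases the complicated stream over their remaining life-table
annuity (for the rare CRC+IBD overlap the annuity uses disease-free
survival, a small overstatement). Undetected adenomas, when their scenario
is on, progress low→high→CRC annually; a conversion in year t contributes,
discounted to baseline, the expected incremental cost/QALY/mortality of a
stage-I CRC case arising at that age and diagnosed after the mean delay.
Detected adenomas are resected and contribute nothing.

Survival and life tables ship as parametric stand-ins (stage-graded
registry-style CRC mortality declining with years since diagnosis;
Gompertz-style all-cause mortality with q(100) = 1); both load from CSV.

## Economics, PSA, scenarios

Outcomes are summed per person and rescaled by scale/n after summation
(exact rational multiplier). INMB = λΔQ − ΔC holds to machine precision and
is antisymmetric; ICERs are reported but flagged whenever the comparison
sits in a dominance quadrant where a ratio misleads. Subgroup outcomes
(default bands <50, 50–69, ≥70 by sex) are computed unscaled and sum
exactly to the population totals. Per-patient scenario INMBs divide by the
population size, not the referred count.

PSA: each run draws one parameter set (beta for probabilities/utilities,
gamma for costs, lognormal for transition-type parameters — standard
health-economics convention), generates a fresh cohort from a run-indexed
seed (population sampling is part of the uncertainty), and evaluates all
strategies on it with common random numbers. Probability cost-effective is
the fraction of runs attaining the maximum net monetary benefit, ties
split equally; credible intervals are empirical percentiles with linear
interpolation. Runs derive seeds as SeedSequence(master, r), so any
execution order gives identical results.

Scenarios are pure config transforms touching only their documented fields
(asserted by a config-diff test). The logistic-model scenario also remaps
risk-kind strategies to the logistic form so thresholds refer to the active
model.

## Problem sizes

Deterministic illustrations in the examples use 30,000–100,000 patients
and the calibration check uses one million; the test suite runs cohorts of
500–20,000 and PSAs of 1–4 runs. These sizes were chosen so the full suite
executes in well under a minute while keeping binomial error small relative
to every asserted tolerance; all engines are vectorised and scale linearly,
so the two-million-patient deterministic analyses and 500 × 100,000 PSAs of
a full study are a matter of letting the same calls run longer.

## What the tests show — and what they do not

The synthetic-data generator reproduces the *structure* of the study
population (correlated skewed marginals, FIT-linked disease prevalence,
risk-based CRC allocation at calibrated incidence) but its grids,
correlations, risk coefficients and all natural-history/economic tables
are stand-ins. Green tests therefore demonstrate correctness of the
machinery (calibration, pairing, accounting identities, monotonicities,
conservation) and qualitative reproduction of the decision structure
(triage beats refer-all on INMB and improves with threshold; the risk
score needs fewer referrals at matched detection; adenoma/IBD consequences
flip the optimum to refer-all; faster progression or doubled delay erodes
triage). They do not validate the absolute magnitudes of costs, QALYs or
deaths for any real population — those require the real aggregate inputs,
loaded through `crctriage.io`.

## Known limitations

No endoscopy capacity/queueing; no within-stage progression; no incident
post-baseline IBD or new adenomas in the base case; CRC recurrence is not
a distinct state; stage-specific survival is not conditioned on route to
diagnosis; IBD streams approximate survival for the rare CRC+IBD overlap;
the blood-count charge fraction has defined meaning only at 0.09 (use the
per-person flag) and 1.0 (charge everyone).
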