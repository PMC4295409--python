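# Methods

`prevmod` estimates and projects the *complete prevalence* of a cancer — the
number of people alive at an index date who were ever diagnosed with it —
from registry data, and decomposes that prevalence into phases of care. The
motivating application is first primary female breast cancer in an
Australian state registry (ages 18–84 at diagnosis, diagnoses 1972–2007,
projection to 2017), and all defaults are set to those study conditions.
This note records the models, the conventions, the synthetic data the
package is tested against, and the choices made where the design was open.

## Time and age conventions

Everything is discretised to integer calendar years. Diagnoses occur at
mid-year; durations are whole years measured mid-year to mid-year; a death
in annual follow-up interval *j* after diagnosis is recorded in calendar
year `year_dx + j` (so a death recorded in the diagnosis year itself cannot
occur — the shortest-lived cases die in interval 1, calendar year
`year_dx + 1`). Prevalence at year *t* counts cases alive at the mid-year of
*t*: a case dying in year *t* is not prevalent at *t*. Ages are attained-age
integers on the closed interval `[age_min, age_max]` (default `[18, 84]`);
an 85+ open class is carried in the population table for the cohort-component
projection but takes no part in any estimate. The population is female only.

These conventions are applied identically in the synthetic-data generator
and in every estimator, which is what makes the generator's direct-count
oracle the exact target of the model chain. With smooth annual inputs the
mid-year discretisation error of the prevalence convolution is second order.

## Incidence: age–period–cohort Poisson models

Diagnosis counts per (single year of age) × (calendar year) cell are Poisson
with a log link and log person-years offset,

    log λ(a, p) = α₀ + Σᵢ αᵢ a′ⁱ + Σⱼ πⱼ p′ʲ + Σₖ γₖ c′ᵏ,   c = p − a.

Nine candidate models APC101…APC303 are fitted (label digits = age, period,
cohort polynomial degrees; period degree 0 throughout, so drift is absorbed
by the cohort terms and the classical APC identification problem does not
arise). Covariates are centred and scaled before powers are taken
(age − 50)/20, (period − 1990)/20, (cohort − 1930)/40 — cubic terms in raw
calendar years are numerically hopeless; the transform is stored with every
fit. Model comparison reports the deviance against the saturated model (the
likelihood-ratio statistic) without penalisation; selection is *reported,
not forced*, and the pipeline pins APC303 by default, overridable in
configuration (`model: auto` takes the deviance front-runner). The chosen
model is evaluated outside the fitting window in both directions; the cohort
covariate extends naturally as year − age. Cells with zero person-years are
dropped, not imputed.

Fitting goes through a standard iteratively-reweighted least-squares GLM;
the test suite cross-checks it coefficient-for-coefficient against an
independently coded Newton–Raphson fit.

## Net survival: Pohar Perme tabulation + mixture cure model

Survival is modelled in two steps, mirroring the tabulate-then-model
workflow used with registry data.

**Step 1 — tabulation.** The actuarial Pohar Perme estimator is computed per
(age group at diagnosis) × (diagnosis period) stratum — defaults: ages
18–49 / 50–69 / 70–84 and periods 1972–80 / 81–89 / 90–95 / 96–2001 /
2002–07 — on annual intervals, with the *cohort approach*: interval *j* is
tabulated only from cases whose potential follow-up reaches its end, so the
most recent period contributes only its fully observable early intervals and
its tail comes from the fitted model rather than the data. Each subject at
risk in interval *j* is weighted by the inverse of her cumulative expected
survival `S_E(j−1)`, computed along the diagnosis-cohort diagonal of the
all-cause life table (age and calendar year advance together, grid edges
clamped). With weighted deaths D′, weighted at-risk N′ and weighted expected
deaths d★ = Σ wᵢ(1 − p★ᵢⱼ), the interval factor is `1 − (D′ − d★)/N′` and
the cumulative estimate is the product of factors. This form reduces
*exactly* to the classic actuarial observed-survival estimator when the life
table is zero (a tested identity). Net-survival estimates may slightly
exceed 1 in strata where observed mortality undercuts expected mortality;
that is a property of net-survival estimators, not an error.

**Step 2 — the cure model.** A mixture cure model

    RS(t; g, y) = c(g, y) + (1 − c(g, y)) · exp(−(λ(g, y) t)^γ_g)

is fitted to the tabulated values per age group by inverse-variance weighted
least squares (standard errors floored at 10⁻³ so early intervals of huge
strata do not dominate), with the cure fraction linear in diagnosis year on
the logit scale and the Weibull scale log-linear in year, both anchored at
the mid-window year. Weibull survival for the non-cured is the canonical
choice; γ = 1 recovers the exponential variant. A cure fraction driven to a
boundary of (0, 1) is flagged rather than silently accepted. The fitted
model defines a survival surface over all diagnosis years: frozen at the
first observed year going backward (stationarity before the window — the
same assumption the backcast incidence and population use) and continuing
the fitted trends forward to the projection horizon.

## Prevalence and mortality: the discrete transition equations

The continuous transition equations linking prevalence and mortality to
incidence and net survival are discretised to the annual mid-year grid. For
report year *t*, attained age *a*, completed duration *d*:

    N(a, t, d) = I(a−d, t−d) · PY(a−d, t−d) · RS(d; g(a−d), t−d) · S_E(a−d, t−d, d)

with `S_E` the expected-survival diagonal product and the survival age group
assigned by age at diagnosis, not attained age. Complete prevalence sums
over *d*; for that sum to be complete, incidence must be backcast
`age_max − age_min` = 66 years before the first report year (diagnosis years
from 1906 for reports from 1972). Person-years before the observation window
are frozen at the first observed year; beyond the window they come from a
cohort-component projection (`count(a+1, t+1) = count(a, t)(1 − qx(a, T))`
with mortality and the youngest-age inflow frozen at the last observed year
*T*, the top class open). Prevalence proportions divide by the 18–84
population only. Reported levels in the first window years are flagged as
backcast-sensitive whenever the observation window is shorter than the
maximum prevalent duration.

Expected cancer deaths in calendar year *t* accumulate each diagnosis
cohort's excess-survival decrement, discounted by background survival:

    D(t) = Σ_{a₀, j≥1} I(a₀, t−j) · PY(a₀, t−j) · S_E(a₀, t−j, j−1) · [RS(j−1) − RS(j)].

Under the interval conventions above this is the exact expectation of the
calendar-year-*t* cancer-death count, with no attained-age cap (a case
diagnosed at 84 may die at 90). The *validation* compares this series with
an external death count that was not used in the modelling; note the
external series must be population mortality — deaths of people diagnosed
before the registry window included — so the registry's own death tally is
only a flagged fallback.

The direct-counting estimator (cases diagnosed in-window, alive at mid-year,
attained age ≤ 84) is the model-free cross-check. It measures
*limited-duration* prevalence: at the last observed year it cannot contain
survivors diagnosed before the window (~3% of complete prevalence in the
synthetic world), so the comparable model quantity is the surface restricted
to in-window durations.

## Phases of care

At any mid-year a prevalent case is in exactly one phase: **initial care**
(duration 0), **post-treatment monitoring** (durations 1 to cutoff−1),
**long-term survivor** (duration ≥ cutoff, default 10 years), or **last year
of life**, which takes precedence: the expected number of prevalent cases
dying of the cancer before the next mid-year, carried per (age, duration)
stratum by the surface (`S_E(d)·[RS(d) − RS(d+1)]` scaled by the diagnosis
cell). When a mortality series is supplied, its *t+1* value rescales the
stratum allocations so a projected mortality trend drives future last-year
counts; allocation proportional to modelled excess deaths is the only
distribution across durations consistent with the survival model.
Allocations are clipped at stratum prevalence (with a warning), and the
bands receive the remainder, so the phases sum to total prevalence exactly —
an identity the tests assert per year and age group.

The **treatment-for-metastases/second-cancer sub-phase** is carved out of
monitoring and long-term survivors. From the registry's subsequent
notifications, the reference-year (default 2006) proportion of each parent
phase with a qualifying event — metastasis outside the 120-day
post-diagnosis lag, or second primary — who then survived at least one
further year is estimated; members dying of the cancer within a year of the
event belong to the last-year phase and leave both numerator and
denominator. Because event records carry calendar years only, the 120-day
lag is applied at annual resolution by discarding metastasis notifications
from the diagnosis year (a mid-year diagnosis plus 120 days stays inside the
calendar year). The proportions are applied to the projected parent phases,
`round(p · parent)` cases move per (year, age-group) cell, and the moved
counts are subtracted from the parents, so totals are conserved exactly.
Registries under-ascertain subsequent metastases, so these proportions are
lower bounds on true treatment need.

Derived display statistics — percent change between two report years, the
average annual *linear* rate (percent change divided by the year gap; a
linear, not compound, rate), and the active-treatment share
(initial + sub-phase over total, rounded to the nearest percent) — live in
`phase_of_care.summary_statistics` and the report layer.

## The synthetic registry and what passing its tests shows

Real extracts of this kind are confidential, so the pipeline is exercised
against a generator whose laws are exactly the structure the analysis
assumes: Poisson cell counts from an age³+cohort³ log-linear rate; mixture
cure net survival (cured cases never die of the cancer; non-cured net death
times Weibull, cure fraction rising on the logit scale by 0.025/year);
background death times drawn independently from a Gompertz life table
(qx = 3·10⁻⁵·e^{0.095·age}, improving 0.6%/year) along the diagnosis
diagonal; metastasis/second-primary notifications at constant annual hazards
(0.012 and 0.008) among survivors. The population is a smooth age profile
(flat to 45, exponential decay after) growing 1.2%/year from 1.55 million
women aged 18–84. The default scenario yields ≈ 90,000 in-window cases over
the 36-year window — the scale of the motivating study — with late-window
5-year net survival near 0.85, and runs in a few seconds. Diagnoses are
simulated from 1906 (with pre-window parameters frozen at 1972 values) so
complete prevalence has its long-duration tail; the emitted registry extract
contains only in-window cases, as a real registry would, while the
uncensored truth drives the direct-count oracles.

Passing the oracle-equivalence tests (model vs direct count within 3% in
total and 5% per age group; expected vs true cancer deaths within 5% MARD)
shows the estimator chain is *self-consistent*: correct when the data follow
the assumed laws. It does not test robustness to what real registries add —
screening-induced incidence bumps and period effects (the generator has
age+cohort structure only), age–period interactions, non-proportional or
non-Weibull excess hazards, dependent censoring, or under-ascertained
events. Second-primary events do not alter a simulated case's survival law.

## Numerical choices and degenerate inputs

- APC fitting: IRLS to tolerance 10⁻¹⁰, 200-iteration cap, non-convergence
  fatal with diagnostics; zero-person-year cells dropped with a warning.
- Cure fit: Levenberg–Marquardt on the weighted residuals; γ parametrised as
  exp(s) for positivity; initial cure guess from the deepest tabulated
  intervals, clipped to (0.05, 0.95) on the probability scale; boundary
  solutions (|logit c| > 7 at the data midpoint) flagged.
- Life-table and population lookups clamp at grid edges (frozen years
  outside the range, oldest age row above the top), which is the documented
  extension rule everywhere a diagonal walks off the grid.
- Empty survival strata are omitted with a warning, never recorded as zero.
- A degenerate (all-zero) population is fatal in the generator; a dead case
  without a death year or cause is a row-level validation error, not a
  guess.
- Determinism: one integer seed drives the generator; identical
  configuration gives byte-identical CSV outputs (asserted in the tests).

## Problem sizes used in the checks

The test suite and the acceptance script run the full default scenario
(~152k simulated cases, ~90k in the registry window; suite ≈ 30 s, script
≈ 5 s). Replicated checks (cure-trend recovery) use 50 synthetic
tabulations with Gaussian noise of standard error 0.01 — the binomial-scale
uncertainty of strata of a few thousand cases — rather than 50 full
registries; estimator-identity checks run on small random cohorts where the
identities are exact.

## Known limitations

- No uncertainty intervals for the projections (bootstrap hooks would fit
  behind the pipeline surface but are out of scope).
- Ages 85+ are excluded throughout, so prevalence understates the full
  burden (the study population groups the oldest ages).
- The mixture-cure parameterisation is a declared stand-in for the family of
  cure models used with tabulated relative survival; recovery tests target
  this parameterisation's own truth.
- The phase definitions are operational simplifications of a survivorship
  trajectory that is not, in reality, a partition.
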