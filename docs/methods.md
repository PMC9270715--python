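# Methods

`artswitch` implements a parametric g-formula (g-computation) analysis of
antiretroviral-therapy (ART) regimen switching in cohorts of people living
with HIV who have developed NNRTI drug resistance. The quantity of interest
is the counterfactual 5-year cumulative mortality risk under four treatment
strategies — the natural course, an immediate switch to an NNRTI-based
regimen, an immediate switch to a PI-based regimen, and a dynamic strategy
that switches to a PI once CD4 drops below 200 cells/µL — together with
risk ratios and risk differences versus the natural course.

## Data model

Follow-up is discretised into 12-month intervals indexed k = 0, 1, 2, …;
interval 0 is the entry interval (the regimen switch that defines time
zero). Each person-interval row carries baseline covariates (age, gender,
education, marital status, transmission route, STD history, TB-treatment
history, HIV-1 subtype), the time-varying CD4 count (cells/µL), viral load
(copies/mL), regimen class (NNRTI vs PI), and death / administrative
censoring indicators. Death is absorbing; intervals are contiguous per
person. Viral load is dichotomised at 10,000 copies/mL for the primary
analysis; the continuous log10 value is retained for a sensitivity variant.

Person-time uses the mid-interval convention: 12 months per fully survived
interval, 6 months for the interval of death, 0 additional months for the
interval of censoring. The convention is isolated in one function
(`cohort.interval_months`) so it can be swapped.

## The g-formula procedure

**Step 1 — pooled models.** Four regressions are fit on the pooled
person-interval table (k ≥ 1), all through `statsmodels`:

| model | family | outcome | time-varying predictors |
|---|---|---|---|
| CD4 | linear | √CD4_k | √CD4_{k−1}, VL-high_{k−1}, PI_{k−1}, k |
| viral load | logistic | VL_k ≥ 10⁴ | CD4_{k−1}/100, VL-high_{k−1}, PI_{k−1}, k |
| switch | logistic | PI_k (on rows with PI_{k−1}=0) | CD4_k/100, VL-high_k, k |
| death | logistic (pooled discrete-time hazard) | died in k | CD4_k/100, VL-high_k, PI_k, k |

Every model additionally includes the baseline covariates (dummy-coded age,
gender, education, marital status, transmission, STD history, TB history).
CD4 is modelled on the square-root scale: the transform stabilises the
variance of a count whose cohort distribution is concentrated near zero and
keeps the Gaussian draw away from the zero boundary, so the linear model is
actually generative (a raw-scale model floored at 0 is truncated for a
large share of draws and its coefficients are not recoverable; the raw
scale remains available via `cd4_sqrt_scale=False`). The regimen process is
one-way — NNRTI→PI switches only; PI is absorbing — because back-switching
is not part of the clinical setting being modelled.

**Step 2 — Monte Carlo standardisation.** A pseudo-population (default
10,000) is drawn with replacement from the observed joint baseline
distribution (preserving baseline covariance for free), then simulated
forward for `horizon_K` intervals (default 10; the 5-year risk is read at
k = 5). Within each interval the update order is CD4 → viral load →
regimen decision → death, the standard g-computation sequencing of
"covariates, then treatment, then outcome". Death is simulated from
interval 1 onward; interval 0 initialises the state (deaths during the
entry interval are likewise absent from the generator, so observed and
simulated curves line up). Under the natural course the regimen is drawn
from the fitted switch model; static strategies force the regimen at every
interval including entry; the dynamic strategy keeps each person's own
regimen until the CD4 trigger fires (checked from entry onward) and is
absorbing thereafter. Simulated individuals are followed to the horizon;
censoring is treated as noninformative and administrative and is not
simulated.

**Step 3 — inference.** Percentile bootstrap, default B = 500 person-level
(cluster) resamples: each replicate refits the four models and resimulates
every strategy with a fresh stream; RR and RD versus the natural course are
computed within each replicate, and 2.5/97.5 percentiles give the 95% CIs.
Point estimates come from the point run, not the bootstrap mean.
Replicates with a degenerate fit (no deaths in the resample, outright
separation failure) are dropped and counted; the run aborts if more than 5%
drop. Quasi-separation — a covariate cell with empirical outcome
probability 0 or 1, common at n ≈ 179 — keeps its saturated fit (flagged
`quasi_separation`); this matches what an unpenalised GLM fit would carry
into the simulation and only the Wald SEs, which the bootstrap does not
use, are unreliable.

## Natural-course diagnostics

The observed per-interval means of CD4, the high-VL fraction, the PI
fraction, and the product-limit cumulative mortality are compared with the
simulated natural-course values (absolute and relative differences). A
caveat established while testing: a pooled death model that retains an
interval main effect largely re-absorbs a single omitted covariate, so
these diagnostics have power mainly against misspecification that distorts
the simulated *trajectories* (e.g. dropping the dominant, time-structured
hazard driver), not against any individual missing term.

## EMB multiple imputation

Missing follow-up CD4 is imputed with the expectation-maximization-bootstrap
scheme: the cohort is pivoted to one row per person (baseline dummies,
CD4_0..CD4_K, log10 VL_0..VL_K — the wide layout is what gives every missing
CD4_k its lagged and lead neighbours as predictors); for each of m = 10
imputations a nonparametric bootstrap resample of persons is drawn, EM
estimates the multivariate-normal mean and covariance on the resample
(warm-started from the full-data EM fit), and each missing CD4 entry of the
original data is drawn from its conditional normal given that row's
observed entries. Imputed CD4 is floored at 0 and rounded to whole cells.
Entries after death or censoring are structurally absent: marginalised out
of the likelihood, never imputed. Only CD4 is ever replaced.

Numerical notes: EM runs on internally standardised columns, so the
convergence tolerance (default 1e-6, maximum 200 iterations) acts on a unit
scale; the observed-data log-likelihood is monotone nondecreasing by
construction and is tracked per iteration. Columns observed only for the
longest-followed persons carry a high fraction of missing information, so
EM convergence is slow there; an unconverged run is flagged, and because
imputation draws parameters from bootstrap resamples anyway, residual
parameter motion well below the bootstrap spread is immaterial. A
degenerate covariance is ridge-regularised (1e-6 · trace/p on the diagonal)
and flagged. Imputation is done once, before the bootstrap; the bootstrap
then runs within each imputed dataset, point estimates average over
imputations, and replicate draws are pooled across imputations before
taking percentiles — the simplest proper scheme, isolated so it can be
swapped.

## Synthetic cohort generator

The generator is the package's test bed: it realises the dependence
structure the analysis assumes (covariates influenced by previous treatment
and baseline variables; death driven by the current state) with explicit
coefficients, so fitting, simulation, bootstrap and imputation can all be
validated against known truth.

Defaults emulate the target setting at study scale: n = 179; baseline
categorical frequencies from the cohort's descriptive table (77.1% male,
50.3% married, 72.6% heterosexual transmission, 61.5% CRF01_AE, …);
baseline CD4 exponential with mean 120 cells/µL (≈81% below 200); baseline
log10 viral load N(4.35, 1) (≈64% at/above 10,000 copies/mL); 44% entering
directly on a PI regimen; administrative follow-up uniform over 6–9 annual
intervals with 2% per-interval dropout (median follow-up ≈ 90 months,
≈15,000 person-months per 179 persons). Transition coefficients were set
once so that CD4 recovers on PI and stagnates on failing NNRTI, viral
suppression is far likelier on PI, switching runs at roughly 15%/year, and
the 5-year natural-course mortality risk lands near 11% (within the 8–15%
band that characterises the setting), crude mortality ≈1.6–1.7 per 1000
person-months. The continuous viral-load value is drawn *consistently with*
the binary suppression state (half-normal offsets on either side of the
threshold), so the binary mechanism — the one the primary analysis fits —
is exactly logistic.

Missingness injection masks post-baseline CD4 (never baseline) under MCAR
or MAR-on-VL (odds of masking multiplied, default ×2, when the concurrent
viral load is high).

**Toy mode** discretises CD4 to {low = 100, high = 400 cells/µL} and VL to
{suppressed = 10³, high = 10⁵ copies/mL} with logistic transitions, making
the state space small enough that the counterfactual risk under any
strategy is computable *exactly* by dynamic programming over the joint
(CD4, VL, regimen, trigger-memory) distribution — a summation over all
covariate/treatment histories. This enumeration, cross-checked in the test
suite against an independent recursive path enumeration, is the oracle for
the Monte Carlo engine and for bootstrap-coverage studies. In continuous
mode an exact oracle is impossible; `exact_risk` instead runs a large
self-contained Monte Carlo from the true coefficients (independent code
path from the engine) and reports its standard error.

What the generator does **not** emulate: irregular visit timing, measurement
error, ART adherence, competing risks, calendar trends, and any calibration
to the real cohort's joint distribution beyond the marginal targets above.
Passing tests therefore demonstrate correctness of the estimator under its
own assumptions — correct model families, exchangeability, no measurement
error — not robustness to their violation in real data.

## Design choices where the design was open

- **Within-interval order** (CD4 → VL → regimen → death) encodes the
  covariates-then-treatment-then-outcome convention; it is centralised in
  one loop in `gformula.simulate` and mirrored by the generator and both
  oracles.
- **Treatment and death models see current-interval covariates** (the
  switch decision responds to the CD4/VL just measured; death follows the
  regimen in force), while CD4/VL transitions condition on the lagged
  state. The fitted models and the generator share this structure exactly.
- **Interval index k** enters all four models as a main effect (a secular
  trend the data could carry); the generator's true k-coefficients are 0.
- **No-effect null**: "zeroing treatment effects" removes the PI
  coefficient from the death, CD4 and VL models — every pathway from
  regimen to death — because with an indirect CD4/VL pathway intact the
  four strategies would still separate; the treatment-assignment model is
  untouched.
- **Eligibility filters** drop persons with no post-baseline CD4 *and* no
  post-baseline VL measurement, and persons with incomplete baseline
  demographics (read as empty CSV fields; numeric sentinels are rejected).
- **Percent rounding** in descriptive tables: one decimal, round-half-up.

## Problem sizes and tolerances in the test suite

Stochastic checks compare against exact oracles at 3 Monte Carlo SEs; the
enumeration-equivalence test confirms any single z-excursion beyond 3 with
one independent rerun at 4× the pseudo-population before counting it a
failure (a 1-in-400 fluctuation does not reproduce; a real bias does).
Coefficient recovery uses 100 replicate cohorts of n = 2000 × 5 intervals;
bootstrap coverage uses 100 toy cohorts of n = 250 with B = 100 (the fast
profile) against the enumeration truth; imputation recovery uses n = 400
with m = 10. These sizes keep each check's Monte Carlo noise well inside
the margins being asserted while the full suite stays lightweight.

## Known limitations

- The pooled logistic hazard approximates the continuous-time hazard on
  12-month intervals; fine-grained timing within an interval is not
  modelled (hence the mid-interval person-time convention).
- Main-effects covariate specifications only; splines/interactions would
  slot into `covariate_spec` lists but are not provided.
- Wald SEs accompany fitted coefficients for diagnostics and recovery
  tests; all reported interval estimates come from the bootstrap.
- The EMB working model is multivariate normal over CD4, log10 VL and
  dummy-coded baseline covariates; only CD4 is imputed, and a normal model
  for dummies is the usual pragmatic approximation of this scheme.
- Natural-course diagnostics validate the joint simulated distribution, not
  each conditional model (see above).
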