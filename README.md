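# artswitch

Parametric g-formula estimation of mortality under antiretroviral-therapy
(ART) regimen-switch strategies in drug-resistant HIV cohorts.

## The problem

People living with HIV who develop resistance to NNRTI-based ART face a
treatment decision: switch to another NNRTI-based regimen, or to a
protease-inhibitor (PI)-based regimen — and if resources are limited, when.
Comparing these strategies from observational cohort data is confounded by
time-varying patient state: CD4 count and viral load influence both the
switch decision and mortality, and are themselves affected by the previous
regimen. Standard regression adjustment is biased when a confounder is also
a causal intermediate; the parametric g-formula (g-computation) handles
this by modelling the covariate and outcome processes jointly and
standardising simulated outcomes over the covariate distribution under each
strategy.

`artswitch` is a tested, reusable implementation of that analysis for
annual-visit person-period cohorts, aimed at epidemiologists and
biostatisticians. It covers the full pipeline:

- validated long-format cohort container with CSV I/O, eligibility filters
  and descriptive statistics (person-time, crude mortality, baseline table);
- a synthetic cohort generator with explicit structural coefficients and an
  **exact enumeration oracle** (binary toy mode) so every stage is testable
  without access to confidential registry data;
- EMB (expectation-maximization-bootstrap) multiple imputation of missing
  follow-up CD4;
- the g-formula engine: pooled models for CD4 (√ scale, linear), high viral
  load (logistic), NNRTI→PI switch (logistic, one-way) and death (pooled
  discrete-time logistic hazard), then Monte Carlo simulation of a
  pseudo-population under each strategy;
- percentile-bootstrap CIs (person-level resampling), risk-ratio /
  risk-difference contrasts versus the natural course, natural-course
  calibration diagnostics, and a config-driven CLI runner with sensitivity
  variants (age ≤ 60, CRF01_AE subtype, continuous viral load).

The four built-in strategies are the natural course, immediate switch to
NNRTI, immediate switch to PI, and "switch to PI once CD4 < 200 cells/µL"
(a dynamic regime with an absorbing trigger).

## The estimator in brief

For intervals k = 1..K, fit pooled models
L(CD4_k | history), logit P(VL_k ≥ 10⁴ | history),
logit P(PI_k | CD4_k, VL_k, on NNRTI at k−1), and the hazard
logit P(D_k = 1 | CD4_k, VL_k, PI_k), all with baseline covariates.
Then draw a pseudo-population from the observed baseline distribution and
simulate forward under strategy g, replacing the regimen assignment by g;
the counterfactual risk is

&nbsp;&nbsp;risk_g(k) = 1 − Π_{j≤k} (1 − h_g(j)),

estimated as the cumulative death fraction of the simulated population.
The 5-year risk is risk_g(5); RR_g = risk_g(5)/risk_nc(5) and
RD_g = risk_g(5) − risk_nc(5) against the natural course, with 95%
percentile-bootstrap CIs (B = 500 person-level resamples, refit and
resimulated per replicate).

## Worked example

```python
import artswitch as a

cohort = a.generate_cohort(a.GeneratorParams(n=2000, seed=3))
config = a.SimConfig(n_mc=10000, horizon_K=10, seed=11)
models = a.fit_models(cohort, config)
for strategy in a.default_strategies():
    curve = a.simulate(models, cohort.baseline(), strategy, config, rng=21)
    print(f"{strategy.name:22s}  {100 * curve.risk_5yr:6.2f}%")
```

prints

```
natural_course           11.60%
immediate_NNRTI          21.43%
immediate_PI              6.45%
PI_if_cd4_lt_200          7.06%
```

— the 5-year cumulative mortality under each strategy: staying on (or
switching to) a failing NNRTI regimen roughly doubles 5-year mortality
relative to the natural course, an immediate PI switch roughly halves it,
and the CD4-triggered switch sits close to the immediate-PI strategy
because most of this cohort is already below 200 cells/µL at entry.
`examples/` contains one short script per capability (descriptives,
bootstrap contrasts, imputation, exact oracle, full pipeline); each prints
its numbers with a line on what they mean.

The CLI wraps the same pipeline:

```bash
artswitch generate --out cohort.csv --seed 3
artswitch run --config config.yaml     # generate/ingest -> impute -> fit ->
                                       # simulate -> bootstrap -> report
artswitch diagnose --run <run_dir>
```

## Layout

```
src/artswitch/
  cohort.py     person-period data model, CSV I/O, validation, descriptives
  design.py     shared feature registry / covariate specifications
  synth.py      synthetic cohort generator + exact-risk oracles
  impute.py     MVN EM and EMB multiple imputation
  gformula.py   pooled model fitting, strategies, Monte Carlo simulation
  inference.py  bootstrap, contrasts, diagnostics, results table
  pipeline.py   config-driven end-to-end runner
  cli.py        thin click CLI (run / generate / diagnose)
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
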