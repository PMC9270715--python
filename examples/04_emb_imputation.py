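"""EMB multiple imputation of missing follow-up CD4 counts.

Masks 20% of post-baseline CD4 values, imputes them with the
expectation-maximization-bootstrap scheme under a multivariate-normal model
over the wide person-level layout (lags and leads of CD4 plus log10 viral
load and baseline covariates), and compares the downstream 5-year
natural-course risk against the complete-data run.
"""

import numpy as np

import artswitch as a

full = a.generate_cohort(a.GeneratorParams(n=400, seed=20))
config = a.SimConfig(n_mc=10000, horizon_K=5, seed=2)
models = a.fit_models(full, config)
complete = 100 * a.simulate(models, full.baseline(), a.Strategy.natural(),
                            config, rng=3).risk_5yr

masked = a.inject_missingness(full, rate=0.2, mechanism="MCAR", seed=4)
n_missing = int(masked.frame.cd4.isna().sum())
imputed = a.emb_impute(masked, a.ImputationSpec(m=10, seed=5))
risks = []
for i, dataset in enumerate(imputed.datasets):
    m_i = a.fit_models(dataset, config)
    risks.append(100 * a.simulate(m_i, dataset.baseline(), a.Strategy.natural(),
                                  config, rng=100 + i).risk_5yr)

print(f"masked CD4 values: {n_missing}")
print(f"complete-data 5-year risk: {complete:.2f}%")
print(f"multiple-imputation mean : {np.mean(risks):.2f}%  "
      f"(per-imputation SD {np.std(risks):.2f})")
# a shift well under 2 percentage points shows the imputation preserves the
# information the mortality models need
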