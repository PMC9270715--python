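# Full analysis configuration for `artswitch run --config examples/config.yaml`.
# Analysis defaults: 10,000-person pseudo-population, 500 bootstrap resamples,
# 10 imputations.  For a quick look use the fast profile noted inline.
seed: 42

input:
  generator:            # or:  path: cohort.csv
    n: 179
    missing_rate: 0.15
    missing_mechanism: MAR_on_VL

filters:
  eligibility: true

imputation:
  enabled: true
  m: 10

sim:
  n_mc: 10000           # fast profile: 2000
  horizon_K: 10

boot:
  B: 500                # fast profile: 100

strategies: default     # natural course, immediate NNRTI, immediate PI,
                        # PI once CD4 < 200

sensitivity: none       # age_le60 | subtype_CRF01AE | vl_continuous

output_dir: artswitch_run
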