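"""Shared fixtures: a hand-written miniature cohort CSV and cached synthetic
cohorts (session-scoped so expensive generation runs once)."""

import io

import pytest

import artswitch as a

# Three-person miniature cohort: one full survivor, one death in interval 2,
# one administratively censored person with a missing follow-up CD4.
TOY_CSV = """\
person_id,k,age_years,gender,education,marital,transmission,std_history,tb_history,subtype,cd4,vl,regimen,died,censored
p1,0,35,male,primary_or_junior,married,heterosexual,no,no,CRF01_AE,150,25000,NNRTI,0,0
p1,1,35,male,primary_or_junior,married,heterosexual,no,no,CRF01_AE,180,12000,NNRTI,0,0
p1,2,35,male,primary_or_junior,married,heterosexual,no,no,CRF01_AE,210,8000,PI,0,0
p2,0,52,female,senior_or_more,other,homosexual,yes,no,CRF07_BC,90,150000,PI,0,0
p2,1,52,female,senior_or_more,other,homosexual,yes,no,CRF07_BC,110,90000,PI,0,0
p2,2,52,female,senior_or_more,other,homosexual,yes,no,CRF07_BC,80,200000,PI,1,0
p3,0,41,male,none,married,other,unknown,yes,other,300,5000,NNRTI,0,0
p3,1,41,male,none,married,other,unknown,yes,other,,7000,NNRTI,0,1
"""


@pytest.fixture
def toy_cohort() -> a.Cohort:
    return a.read_cohort(io.StringIO(TOY_CSV))


@pytest.fixture(scope="session")
def default_params() -> a.GeneratorParams:
    return a.GeneratorParams(n=400, seed=20)


@pytest.fixture(scope="session")
def synthetic_cohort(default_params) -> a.Cohort:
    return a.generate_cohort(default_params)


@pytest.fixture(scope="session")
def toy_params() -> a.GeneratorParams:
    return a.GeneratorParams(n=300, K_max=5, seed=8).with_toy_defaults()


@pytest.fixture(scope="session")
def toy_mode_cohort(toy_params) -> a.Cohort:
    return a.generate_cohort(toy_params)


@pytest.fixture(scope="session")
def fitted_models(synthetic_cohort):
    cfg = a.SimConfig(n_mc=2000, horizon_K=10, seed=5)
    return a.fit_models(synthetic_cohort, cfg), cfg
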