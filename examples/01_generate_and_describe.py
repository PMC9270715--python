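"""Generate a synthetic drug-resistance cohort and describe it.

Draws a 179-person cohort with annual follow-up (the structure of a
provincial ART drug-resistance cohort: baseline CD4 mostly below 200
cells/uL, majority high viral load, one-way NNRTI->PI switching, death as
absorbing outcome) and prints its person-time, crude mortality rate and part
of the baseline frequency table.
"""

import artswitch as a

cohort = a.generate_cohort(a.GeneratorParams(n=179, seed=7))
months, deaths = a.person_time(cohort)
rate = a.crude_mortality_rate(deaths, months)

print(f"persons: {cohort.n_persons}, person-period rows: {len(cohort)}")
print(f"person-months: {months:.0f}, deaths: {deaths}")
print(f"crude mortality: {rate:.2f} per 1000 person-months")
# a crude rate near 1.7/1000 pm and ~80% of entries below 200 cells/uL mirror
# the kind of cohort this analysis targets
table = a.baseline_table(cohort)
print(table[table.variable.isin(["gender", "baseline_cd4_group"])].to_string(index=False))
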