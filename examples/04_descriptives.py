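"""Descriptive tables over the selected hyponatremia cases.

Age, sex and reporter-occupation distributions (denominator: distinct
selected reports), the annual reporting trend per drug, the top
reporting countries, and the outcome distribution with a seriousness
rollup.  With the default generator settings these recover the
configured demographic masses (e.g. most cases aged 65+, more male than
female, hospitalization the most frequent outcome).
"""

from faerspv import (
    SimulationConfig,
    deduplicate_cases,
    generate_reports,
    load_drug_dictionary,
    load_smq,
    select_cases,
)
from faerspv.descriptives import (
    annual_trend,
    country_ranking,
    demographic_summary,
    outcome_distribution,
)

reports, _ = generate_reports(SimulationConfig(n_reports=50_000, seed=3))
cases = deduplicate_cases(reports)
smq = load_smq()
dictionary = load_drug_dictionary()
casesets = {
    drug: select_cases(cases, smq, dictionary, drug)
    for drug in ("NIVOLUMAB", "PEMBROLIZUMAB", "ATEZOLIZUMAB")
}

for name, table in demographic_summary(casesets).items():
    print(f"\n== {name} ==")
    print(table.to_string(index=False))

print("\n== annual trend ==")
print(annual_trend(casesets).to_string(index=False))
print("\n== top countries ==")
print(country_ranking(casesets, top=5).to_string(index=False))
print("\n== outcomes ==")
print(outcome_distribution(casesets).to_string(index=False))
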