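"""Consistency of obesity across three age windows (2-<4, 6-<8, >=10 y).

Children with a retained visit in each window are classified into the
eight yes/no obesity patterns; percentages are reported against the
whole subcohort and the early-/late-obesity subgroups.
"""

from growthtrack import (
    SyntheticConfig,
    attach_bmi_metrics,
    clean,
    extract_three_windows,
    generate_cohort,
    persistence_patterns,
    retained_visits,
    synthetic_reference,
)

cohort = generate_cohort(SyntheticConfig(n_children=8000, seed=7, visits_mean=9.0))
cleaned, _ = clean(cohort.visits)
records = attach_bmi_metrics(retained_visits(cleaned), synthetic_reference())
triples = extract_three_windows(records)
print(f"children with visits in all three windows: {len(triples)}")

table = persistence_patterns(triples)
cols = ["w1_obese", "w2_obese", "w3_obese", "n", "pct_total", "pct_early_obesity", "pct_late_obesity"]
print(table[cols].round(1).to_string(index=False))

# The never-obese pattern dominates; among children obese at 2-<4 y a
# large share remains obese at both later windows, while a substantial
# fraction of children obese at >=10 y were not obese in either earlier
# window -- the reason early screening has limited sensitivity.
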