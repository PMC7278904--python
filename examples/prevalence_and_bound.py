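"""Prevalence by age group (one record per child per cell) and the
prevalence-ratio upper bound on early-screening sensitivity.

When prevalence rises with age, the sensitivity of obesity at age 2 for
obesity at older ages can be no larger than the ratio of the two
prevalences -- regardless of how strongly obesity tracks.
"""

from growthtrack import (
    SyntheticConfig,
    attach_bmi_metrics,
    clean,
    generate_cohort,
    max_sensitivity_bound,
    prevalence,
    retained_visits,
    sample_one_per_cell,
    synthetic_reference,
)

cohort = generate_cohort(SyntheticConfig(n_children=5000, seed=7))
cleaned, _ = clean(cohort.visits)
records = attach_bmi_metrics(retained_visits(cleaned), synthetic_reference())

sampled = sample_one_per_cell(records, age_bins=[2, 3, 9, 19.01], seed=7)
by_age = prevalence(sampled, by=["age_group"])
print(by_age.round(1).to_string(index=False))

young = by_age.iloc[0]["prevalence_pct"]
old = by_age.iloc[-1]["prevalence_pct"]
bound = max_sensitivity_bound(young, old)
print(
    f"\nprevalence {young:.1f}% at 2-<3 y vs {old:.1f}% at >=9 y "
    f"-> sensitivity of obesity at 2 for later obesity is at most {bound:.0f}%"
)
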