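"""Derive the three indicators of deteriorating health reserves.

Allostatic load counts how many of 14 biomarkers fall in the sex-specific
high-risk quartile (low 0-2 / middle 3-4 / high 5-14); the abbreviated
CIS-r sums 14 symptom domains with a case cutoff of 9; chronic widespread
pain applies the ACR-1990 widespreadness-plus-chronicity conjunction.
"""

import healthreserves as hr

cohort, _ = hr.apply_exclusions(
    hr.generate_cohort(hr.GeneratorConfig(n_individuals=10_000, seed=1))
)
indicators = hr.score_cohort(cohort)

print(indicators.head())
print("\nAL categories (%):")
print((100 * indicators["al_category"].value_counts(normalize=True)).round(1))
print("\nCIS-r cases (%):",
      round(100 * (indicators["cisr_class"] == "common_mental_disorder").mean(), 1))
print("CWP prevalence (%):", round(100 * indicators["cwp"].mean(), 1))

# Roughly a quarter of individuals sit in the high allostatic-load band,
# ~11% screen positive for a common mental disorder and ~28% report
# chronic widespread pain — the mid-life frequencies the generator emulates.
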