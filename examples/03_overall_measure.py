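"""Compose the overall health measure and tabulate its distribution.

The three indicators are rescaled to equal weight (AL -> 0/0.5/1, the two
binaries -> 0/1) and summed; the value in {0, 0.5, ..., 3} is grouped as
optimal (0), medium (0.5-1) or impaired (1.5-3).
"""

import healthreserves as hr

cohort, _ = hr.apply_exclusions(
    hr.generate_cohort(hr.GeneratorConfig(n_individuals=10_000, seed=1))
)
indicators = hr.score_cohort(cohort)
overall = hr.compose(indicators)
tables = hr.tabulate(overall, indicators)

print("by category:\n", tables["by_category"].round(2), sep="")
print("\nby value:\n", tables["by_value"].round(2), sep="")
print("\nindicator combinations:\n", tables["by_combination"].round(2), sep="")

# 'Optimal' individuals have no deteriorated reserve at all; 'medium' means
# exactly one mild deterioration; 'impaired' accumulates 1.5+ points across
# reserves.  The combination table shows which indicator patterns build each
# category.
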