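"""Published summary counts from the 1958 British birth cohort study sample.

The individual-level data of the National Child Development Study (NCDS 58)
are restricted-access; these are the printed summary tables of its mid-life
biomedical-survey analysis sample (n = 7,043), used as exact fixtures for
validating the composition and association machinery.
"""

from __future__ import annotations

import pandas as pd

from .criterion_validity import ContingencyTable2x2

#: The 12 observed (AL category, CIS-r class, CWP) combinations and their
#: counts in the analysis sample.
INDICATOR_COMBINATION_COUNTS: tuple[tuple[str, str, bool, int], ...] = (
    ("low", "no_disorder", False, 2153),
    ("middle", "no_disorder", False, 1524),
    ("high", "no_disorder", False, 984),
    ("low", "common_mental_disorder", False, 169),
    ("low", "no_disorder", True, 718),
    ("middle", "common_mental_disorder", False, 126),
    ("middle", "no_disorder", True, 499),
    ("high", "common_mental_disorder", False, 96),
    ("low", "common_mental_disorder", True, 122),
    ("high", "no_disorder", True, 396),
    ("middle", "common_mental_disorder", True, 118),
    ("high", "common_mental_disorder", True, 138),
)

#: Cross-tabulation of each indicator against dichotomised self-rated health
#: two years later: (cases = fair/poor/very poor, non-cases = excellent/good)
#: counts by indicator level.
SRH_CROSSTAB_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    # level: (poor-SRH count, good-SRH count)
    "al_category": {
        "low": (463, 2699),
        "middle": (537, 1730),
        "high": (517, 1097),
    },
    "cisr_class": {
        "no_disorder": (1265, 5365),
        "common_mental_disorder": (252, 161),
    },
    "cwp": {"no": (813, 4239), "yes": (704, 1287)},
}


def srh_table(indicator: str, positive_levels: tuple[str, ...]) -> ContingencyTable2x2:
    """2x2 table of an indicator (given positive levels) vs poor SRH."""
    counts = SRH_CROSSTAB_COUNTS[indicator]
    a = sum(c[0] for lvl, c in counts.items() if lvl in positive_levels)
    b = sum(c[0] for lvl, c in counts.items() if lvl not in positive_levels)
    c_ = sum(c[1] for lvl, c in counts.items() if lvl in positive_levels)
    d = sum(c[1] for lvl, c in counts.items() if lvl not in positive_levels)
    return ContingencyTable2x2(a=a, b=b, c=c_, d=d)


def indicator_combination_table() -> pd.DataFrame:
    """The combination counts as a tidy frame."""
    return pd.DataFrame(
        INDICATOR_COMBINATION_COUNTS,
        columns=["al_category", "cisr_class", "cwp", "n"],
    )
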