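"""The three indicators of deteriorating health reserves.

* **Allostatic load (AL)** — physiological reserve.  Each of 14 biomarkers is
  dichotomised at its sex-specific risk-side quartile (strictly beyond the
  boundary); the sum of the 14 flags (0-14) is categorised low (0-2),
  middle (3-4), high (5-14).
* **Abbreviated CIS-r** — socioemotional reserve.  The sum of 14 symptom
  domain scores; a score at or above the cutoff (default 9) classifies a
  common mental disorder.
* **Chronic widespread pain (CWP)** — physical reserve.  The ACR-1990
  fibromyalgia criterion: pain lasting three months or longer, above and
  below the waist, on both body sides and in the axial skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import CISR_DOMAINS, CISR_DOMAIN_MAX, PAIN_REGIONS

System = Literal[
    "neuroendocrine", "immune_inflammatory", "metabolic", "cardio_respiratory"
]
RiskDirection = Literal["upper_quartile", "lower_quartile"]

AL_CATEGORIES = ("low", "middle", "high")
CISR_CLASSES = ("no_disorder", "common_mental_disorder")


class StratificationError(ValueError):
    """A sex stratum has too few non-missing values to locate a quartile."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """One biomarker of the allostatic-load panel.

    ``risk_direction`` states which tail of the sex-specific distribution is
    coded as high risk: ``upper_quartile`` flags readings strictly above Q3,
    ``lower_quartile`` strictly below Q1.
    """

    name: str
    system: System
    risk_direction: RiskDirection


#: Default 14-biomarker panel across the four physiological systems.
#: Risk directions follow the usual allostatic-load conventions (protective
#: analytes IGF-1, HDL and peak expiratory flow flagged in the lower tail;
#: a blunted cortisol diurnal decline, i.e. low t1-t2, flagged as risk) and
#: are overridable since the literature varies.
DEFAULT_PANEL: tuple[BiomarkerSpec, ...] = (
    BiomarkerSpec("cortisol_t1", "neuroendocrine", "upper_quartile"),
    BiomarkerSpec("cortisol_t1_t2", "neuroendocrine", "lower_quartile"),
    BiomarkerSpec("igf1", "immune_inflammatory", "lower_quartile"),
    BiomarkerSpec("crp", "immune_inflammatory", "upper_quartile"),
    BiomarkerSpec("fibrinogen", "immune_inflammatory", "upper_quartile"),
    BiomarkerSpec("ige", "immune_inflammatory", "upper_quartile"),
    BiomarkerSpec("hdl", "metabolic", "lower_quartile"),
    BiomarkerSpec("ldl", "metabolic", "upper_quartile"),
    BiomarkerSpec("triglycerides", "metabolic", "upper_quartile"),
    BiomarkerSpec("hba1c", "metabolic", "upper_quartile"),
    BiomarkerSpec("sbp", "cardio_respiratory", "upper_quartile"),
    BiomarkerSpec("dbp", "cardio_respiratory", "upper_quartile"),
    BiomarkerSpec("heart_rate", "cardio_respiratory", "upper_quartile"),
    BiomarkerSpec("peak_flow", "cardio_respiratory", "lower_quartile"),
)

RISK_DIRECTIONS: dict[str, RiskDirection] = {
    s.name: s.risk_direction for s in DEFAULT_PANEL
}


def dichotomize_biomarker(
    values: Sequence[float] | pd.Series,
    sex_labels: Sequence[str] | pd.Series,
    spec: BiomarkerSpec,
) -> pd.Series:
    """Flag individuals strictly beyond the sex-specific risk-side quartile.

    Quartiles are the linear-interpolation sample quantiles at p = 0.25 /
    0.75 computed within each sex stratum over non-missing readings.  Values
    exactly at the boundary are coded low risk (0).  Missing readings yield
    missing flags.

    Returns a float series of 0.0 / 1.0 / NaN aligned with the input.

    Raises
    ------
    StratificationError
        If any sex stratum has fewer than 4 non-missing readings.
    """
    idx = values.index if isinstance(values, pd.Series) else None
    values = pd.Series(np.asarray(values, dtype=float), index=idx)
    sex = pd.Series(np.asarray(sex_labels, dtype=object), index=idx)
    if len(values) != len(sex):
        raise ValueError("values and sex_labels must have equal length")

    flags = pd.Series(np.nan, index=values.index)
    for stratum in pd.unique(sex):
        mask = (sex == stratum).to_numpy()
        v = values[mask]
        ok = v.notna()
        if ok.sum() < 4:
            raise StratificationError(
                f"sex stratum {stratum!r} has {int(ok.sum())} non-missing "
                f"values for {spec.name!r}; at least 4 required"
            )
        if spec.risk_direction == "upper_quartile":
            q = np.quantile(v[ok], 0.75, method="linear")
            risk = v > q
        else:
            q = np.quantile(v[ok], 0.25, method="linear")
            risk = v < q
        flags[mask] = np.where(ok, risk.astype(float), np.nan)
    return flags


def allostatic_load(flags: pd.DataFrame) -> pd.DataFrame:
    """Sum 14 binary risk flags into the AL score and its category.

    ``flags`` holds one column per biomarker (0/1, NaN for missing).  Any
    missing flag makes the individual unscorable: both outputs are missing
    (the complete-case convention used downstream).

    Returns a frame with ``al_score`` (nullable integer) and ``al_category``
    (categorical low/middle/high).
    """
    if flags.shape[1] != 14:
        raise ValueError(f"expected 14 flag columns, got {flags.shape[1]}")
    arr = flags.to_numpy(dtype=float)
    complete = ~np.isnan(arr).any(axis=1)
    score = np.where(complete, np.nansum(arr, axis=1), np.nan)
    out = pd.DataFrame(index=flags.index)
    out["al_score"] = pd.array(score, dtype="Int64")
    out["al_category"] = pd.Categorical(
        np.select(
            [score <= 2, score <= 4, score >= 5],
            ["low", "middle", "high"],
            default=None,
        ),
        categories=AL_CATEGORIES,
        ordered=True,
    )
    return out


def al_category_of(score: int) -> str:
    """Map one AL score to its category: 0-2 low, 3-4 middle, 5-14 high."""
    if not 0 <= score <= 14:
        raise ValueError(f"AL score must lie in 0-14, got {score}")
    if score <= 2:
        return "low"
    if score <= 4:
        return "middle"
    return "high"


def cisr_classify(
    domain_scores: pd.DataFrame, cutoff: int = 9
) -> pd.DataFrame:
    """Sum the 14 CIS-r domain scores and apply the case cutoff.

    Thirteen domains are scored 0-4 and suicidal ideation 0-5; an
    out-of-range score raises a ``ValueError`` naming the offending domain.
    The class is ``common_mental_disorder`` iff score >= ``cutoff``
    (inclusive by default; the cutoff is configurable).  Rows with any
    missing domain are unscorable (missing score and class).
    """
    cols = list(domain_scores.columns)
    if len(cols) != len(CISR_DOMAINS):
        raise ValueError(
            f"expected {len(CISR_DOMAINS)} domain columns, got {len(cols)}"
        )
    for col in cols:
        name = col.removeprefix("cisr_")
        hi = CISR_DOMAIN_MAX.get(name, 4)
        v = domain_scores[col]
        bad = v.dropna()
        bad = bad[(bad < 0) | (bad > hi) | (bad != bad.astype(int))]
        if len(bad):
            raise ValueError(
                f"domain {name!r} has scores outside 0-{hi}: "
                f"{sorted(bad.unique())[:5]}"
            )
    arr = domain_scores.to_numpy(dtype=float)
    complete = ~np.isnan(arr).any(axis=1)
    score = np.where(complete, np.nansum(arr, axis=1), np.nan)
    out = pd.DataFrame(index=domain_scores.index)
    out["cisr_score"] = pd.array(score, dtype="Int64")
    out["cisr_class"] = pd.Categorical(
        np.select(
            [score >= cutoff, score < cutoff],
            ["common_mental_disorder", "no_disorder"],
            default=None,
        ),
        categories=CISR_CLASSES,
    )
    return out


def classify_cwp(
    pain_duration_3mo: Sequence[bool] | pd.Series,
    pain_regions: pd.DataFrame,
) -> pd.Series:
    """ACR-1990 chronic widespread pain: chronicity AND full widespreadness.

    True iff the >= 3-month duration flag and all five region summaries
    (above/below waist, left/right side, axial skeleton) hold.
    """
    missing = set(PAIN_REGIONS) - {
        c.removeprefix("pain_") for c in pain_regions.columns
    }
    if missing:
        raise ValueError(f"pain_regions missing columns {sorted(missing)}")
    dur = pd.Series(pain_duration_3mo).astype(bool)
    dur.index = pain_regions.index
    return dur & pain_regions.astype(bool).all(axis=1)


def score_cohort(
    cohort: pd.DataFrame,
    panel: Iterable[BiomarkerSpec] = DEFAULT_PANEL,
    cisr_cutoff: int = 9,
) -> pd.DataFrame:
    """Derive all three reserve indicators for a cohort table.

    Expects the generator's column schema (biomarker columns named as in the
    panel, ``cisr_<domain>`` columns, ``pain_duration_3mo`` and
    ``pain_<region>`` columns, plus ``sex``).  Returns one row per input row
    with ``al_score``, ``al_category``, ``cisr_score``, ``cisr_class`` and
    ``cwp`` (``id`` is carried through when present).
    """
    panel = tuple(panel)
    if len(panel) != 14:
        raise ValueError(f"biomarker panel must have 14 entries, got {len(panel)}")
    flags = pd.DataFrame(index=cohort.index)
    for spec in panel:
        flags[spec.name] = dichotomize_biomarker(
            cohort[spec.name], cohort["sex"], spec
        )
    out = allostatic_load(flags)
    cis = cisr_classify(
        cohort[[f"cisr_{d}" for d in CISR_DOMAINS]], cutoff=cisr_cutoff
    )
    out = out.join(cis)
    out["cwp"] = classify_cwp(
        cohort["pain_duration_3mo"],
        cohort[[f"pain_{r}" for r in PAIN_REGIONS]],
    )
    if "id" in cohort.columns:
        out.insert(0, "id", cohort["id"])
    return out
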