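"""Comparative analyses probing the robustness of the composite measure.

Variants rerun the full criterion-validity estimate set under a perturbed
design: an alternative grouping of the composite values, recomposed measures
built from user-supplied components, a negative-control split of the sample
by survey response-month parity (month of response should carry no health
information, so both halves should show the same trend), and self-rated
health measured at ages 50 or 55 instead of 46.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import overall_health as _overall
from .criterion_validity import (
    ValidationResult,
    build_analysis_table,
    results_frame,
    validity_report,
)

#: Built-in variant names.
VARIANTS = (
    "alt_grouping",
    "odd_months",
    "even_months",
    "srh_age_50",
    "srh_age_55",
)


@dataclass(frozen=True)
class RecomposedVariant:
    """A user-defined recomposition of the overall measure."""

    label: str
    component_specs: tuple[_overall.ComponentSpec, ...]
    grouping: _overall.GroupingScheme = _overall.DEFAULT_GROUPING


@dataclass
class ComparisonRun:
    """One variant's estimate set."""

    label: str
    variant: str
    n: int
    results: list[ValidationResult] = field(default_factory=list)


def split_by_response_month(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition by survey response-month parity (odd sample, even sample).

    The two subsets are disjoint and exhaustive.  A missing month is a
    validation error: parity would be undefined.
    """
    month = cohort["response_month"]
    if month.isna().any():
        raise ValueError("response_month is missing for some records")
    m = month.astype(int)
    if not m.between(1, 12).all():
        raise ValueError("response_month must lie in 1-12")
    odd = cohort[m % 2 == 1]
    even = cohort[m % 2 == 0]
    return odd, even


def _estimates(analysis: pd.DataFrame, followup_years: float) -> list[ValidationResult]:
    report = validity_report(analysis, followup_years=followup_years)
    rows = report.adjusted_estimates
    out = []
    for _, r in rows.iterrows():
        out.append(
            ValidationResult(
                exposure=r["exposure"], level=r["level"], reference=r["reference"],
                outcome=r["outcome"], estimate_type=r["type"], point=r["point"],
                ci_low=r["ci_low"], ci_high=r["ci_high"], ci_level=r["ci_level"],
                adjustment=tuple(r["adjustment"].split("+")) if r["adjustment"] else (),
                n=r["n"], p_value=r["p_value"],
            )
        )
    return out


def run_comparisons(
    cohort: pd.DataFrame,
    variants: Sequence[str | RecomposedVariant] = (),
    followup_years: float = 14.0,
    cisr_cutoff: int = 9,
) -> tuple[list[ComparisonRun], pd.DataFrame]:
    """Primary analysis plus the requested variants, side by side.

    ``cohort`` is a raw (generator-schema) table; each run scores it under
    the variant's design and reruns the sex-adjusted OR/HR estimate set.
    Returns the runs and a tidy comparison table keyed by run label.
    """
    runs: list[ComparisonRun] = []

    def add_run(label: str, variant: str, analysis: pd.DataFrame) -> None:
        runs.append(
            ComparisonRun(
                label=label, variant=variant, n=len(analysis),
                results=_estimates(analysis, followup_years),
            )
        )

    primary = build_analysis_table(
        cohort, cisr_cutoff=cisr_cutoff, followup_years=followup_years
    )
    add_run("primary", "primary", primary)

    for v in variants:
        if isinstance(v, RecomposedVariant):
            analysis = build_analysis_table(
                cohort, cisr_cutoff=cisr_cutoff, followup_years=followup_years
            )
            rec = _overall.recompose(analysis, v.component_specs, v.grouping)
            analysis = analysis.assign(value=rec["value"], category=rec["category"])
            analysis = analysis[analysis["value"].notna()]
            add_run(v.label, "recomposed_measure", analysis)
        elif v == "alt_grouping":
            analysis = build_analysis_table(
                cohort, cisr_cutoff=cisr_cutoff,
                scheme=_overall.MERGED_GROUPING, followup_years=followup_years,
            )
            add_run(v, v, analysis)
        elif v in ("odd_months", "even_months"):
            odd, even = split_by_response_month(cohort)
            sub = odd if v == "odd_months" else even
            add_run(v, v, build_analysis_table(
                sub, cisr_cutoff=cisr_cutoff, followup_years=followup_years
            ))
        elif v in ("srh_age_50", "srh_age_55"):
            col = "srh_50" if v == "srh_age_50" else "srh_55"
            add_run(v, v, build_analysis_table(
                cohort, cisr_cutoff=cisr_cutoff, srh_column=col,
                followup_years=followup_years,
            ))
        else:
            raise ValueError(f"unknown variant {v!r}")

    frames = []
    for run in runs:
        df = results_frame(run.results)
        df.insert(0, "run", run.label)
        df.insert(1, "variant", run.variant)
        df.insert(2, "n_run", run.n)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return runs, table
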