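"""The overall health measure: rescale, sum, and group the three indicators.

Each indicator of deteriorating health reserves is rescaled to span [0, 1]
with equal weight: the three allostatic-load categories map to 0 / 0.5 / 1,
and the two binary indicators (common mental disorder, chronic widespread
pain) to 0 / 1.  Their sum takes values {0, 0.5, ..., 3} and is grouped as
optimal (0), medium (0.5-1), impaired (1.5-3).  Values are carried as exact
half-units internally so category boundaries never hit floating-point noise.

``recompose`` generalises the construction to arbitrary ordinal components
rescaled to [0, 1], which hosts alternative composite formulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AL_VALUES = {"low": Fraction(0), "middle": Fraction(1, 2), "high": Fraction(1)}


@dataclass(frozen=True)
class GroupingScheme:
    """Total, order-respecting map from composite values to category labels.

    ``intervals`` lists ``(label, lo, hi)`` with inclusive bounds; they must
    be disjoint, ordered, and jointly cover every value the composite can
    take.
    """

    name: str
    intervals: tuple[tuple[str, Fraction, Fraction], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"interval {label!r} has lo > hi")
            if prev_hi is not None and lo <= prev_hi:
                raise ValueError("grouping intervals must be ordered and disjoint")
            prev_hi = hi

    def category_of(self, value: Fraction | float) -> str:
        v = Fraction(value).limit_denominator(1000)
        for label, lo, hi in self.intervals:
            if lo <= v <= hi:
                return label
        raise ValueError(f"value {value} not covered by grouping {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.intervals)


def _f(x) -> Fraction:
    return Fraction(x).limit_denominator(1000)


#: The primary grouping: optimal [0] / medium [0.5-1] / impaired [1.5-3].
DEFAULT_GROUPING = GroupingScheme(
    "default",
    (
        ("optimal", _f(0), _f(0)),
        ("medium", _f(0.5), _f(1)),
        ("impaired", _f(1.5), _f(3)),
    ),
)

#: Alternative grouping merging the two lowest values (0 and 0.5).
MERGED_GROUPING = GroupingScheme(
    "merged_low",
    (
        ("optimal_merged", _f(0), _f(0.5)),
        ("medium", _f(1), _f(1)),
        ("impaired", _f(1.5), _f(3)),
    ),
)

GROUPINGS = {g.name: g for g in (DEFAULT_GROUPING, MERGED_GROUPING)}


def compose(
    indicators: pd.DataFrame, scheme: GroupingScheme = DEFAULT_GROUPING
) -> pd.DataFrame:
    """Rescale-and-sum the three indicators into the overall health measure.

    ``indicators`` needs columns ``al_category`` (low/middle/high),
    ``cisr_class`` (no_disorder/common_mental_disorder) and ``cwp`` (bool).
    Individuals with any missing component are unscorable (NaN value and
    category).  Returns ``value`` (float in {0, 0.5, ..., 3}) and
    ``category`` per the grouping scheme.
    """
    al = indicators["al_category"].map({"low": 0, "middle": 1, "high": 2})
    cis = indicators["cisr_class"].map(
        {"no_disorder": 0, "common_mental_disorder": 2}
    )
    cwp = indicators["cwp"]
    # half-units: value*2, so every quantity is an exact small integer
    half = (
        pd.to_numeric(al, errors="coerce")
        + pd.to_numeric(cis, errors="coerce")
        + np.where(cwp.isna(), np.nan, cwp.astype(float) * 2)
    )
    cat_of = {h: scheme.category_of(Fraction(h, 2)) for h in range(7)}
    out = pd.DataFrame(index=indicators.index)
    out["value"] = half / 2.0
    out["category"] = pd.Categorical(
        pd.Series(half, index=indicators.index).map(cat_of),
        categories=list(dict.fromkeys(scheme.labels)),
        ordered=True,
    )
    return out


def tabulate(
    overall: pd.DataFrame, indicators: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Distribution of the measure and its constituent indicator combinations.

    Returns three frames — ``by_category``, ``by_value`` and
    ``by_combination`` (value x AL x CIS-r x CWP) — each with counts and
    percentages of the scorable individuals.  Category counts equal the sums
    of their constituent cells by construction.
    """
    ok = overall["value"].notna()
    n = int(ok.sum())

    def with_pct(counts: pd.Series) -> pd.DataFrame:
        df = counts.rename("n").to_frame()
        df["pct"] = 100.0 * df["n"] / n if n else 0.0
        return df

    by_cat = with_pct(overall.loc[ok, "category"].value_counts(sort=False))
    by_val = with_pct(
        overall.loc[ok, "value"].value_counts(sort=False).sort_index()
    )
    combo = pd.DataFrame(
        {
            "value": overall.loc[ok, "value"],
            "category": overall.loc[ok, "category"],
            "al_category": indicators.loc[ok, "al_category"],
            "cisr_class": indicators.loc[ok, "cisr_class"],
            "cwp": indicators.loc[ok, "cwp"].astype(bool),
        }
    )
    by_combo = (
        combo.groupby(
            ["value", "category", "al_category", "cisr_class", "cwp"],
            observed=True,
        )
        .size()
        .rename("n")
        .reset_index()
        .sort_values(["value", "al_category"], kind="stable")
        .reset_index(drop=True)
    )
    by_combo["pct"] = 100.0 * by_combo["n"] / n if n else 0.0
    return {"by_category": by_cat, "by_value": by_val, "by_combination": by_combo}


@dataclass(frozen=True)
class ComponentSpec:
    """One ordinal component of a recomposed measure.

    ``levels`` orders the categories from best to worst; ``values`` gives
    each level's rescaled contribution, spanning [0, 1] (defaults to evenly
    spaced).
    """

    column: str
    levels: tuple
    values: tuple[Fraction, ...] = field(default=())

    def resolved_values(self) -> tuple[Fraction, ...]:
        if self.values:
            vals = tuple(_f(v) for v in self.values)
        elif len(self.levels) == 1:
            vals = (Fraction(0),)
        else:
            k = len(self.levels) - 1
            vals = tuple(Fraction(i, k) for i in range(len(self.levels)))
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(
                f"component {self.column!r} has rescaled values outside [0, 1]"
            )
        if len(vals) != len(self.levels):
            raise ValueError(
                f"component {self.column!r}: {len(self.levels)} levels but "
                f"{len(vals)} values"
            )
        return vals


#: The default three components, reproducing ``compose``.
DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("al_category", ("low", "middle", "high")),
    ComponentSpec("cisr_class", ("no_disorder", "common_mental_disorder")),
    ComponentSpec("cwp", (False, True)),
)


def recompose(
    indicator_table: pd.DataFrame,
    component_specs: Sequence[ComponentSpec] = DEFAULT_COMPONENTS,
    grouping: GroupingScheme = DEFAULT_GROUPING,
) -> pd.DataFrame:
    """Generic rescale-to-[0,1]-and-sum over arbitrary ordinal components.

    Reproduces ``compose`` when given the default three components and
    grouping.  Sums are exact rationals; the grouping must cover every
    reachable sum.
    """
    total = pd.Series(Fraction(0), index=indicator_table.index, dtype=object)
    missing = pd.Series(False, index=indicator_table.index)
    for spec in component_specs:
        vals = dict(zip(spec.levels, spec.resolved_values()))
        col = indicator_table[spec.column].astype(object)
        mapped = col.map(vals)
        unknown = col.notna() & mapped.isna()
        if unknown.any():
            raise ValueError(
                f"component {spec.column!r} has levels outside its spec: "
                f"{sorted(col[unknown].unique())[:5]}"
            )
        missing |= col.isna()
        total = total + mapped.fillna(Fraction(0))
    out = pd.DataFrame(index=indicator_table.index)
    out["value"] = np.where(missing, np.nan, [float(v) for v in total])
    cats = pd.Series(
        [None if m else grouping.category_of(v)
         for v, m in zip(total, missing)],
        index=indicator_table.index,
    )
    out["category"] = pd.Categorical(
        cats, categories=list(dict.fromkeys(grouping.labels)), ordered=True
    )
    return out


def expand_counts(
    cells: Iterable[tuple[str, str, bool, int]]
) -> pd.DataFrame:
    """Expand (AL, CIS-r, CWP, count) cells into one row per individual.

    Convenience for feeding published cross-tabulation cell counts through
    ``compose``/``tabulate``.
    """
    rows = []
    for al, cis, cwp, n in cells:
        rows.extend([(al, cis, cwp)] * int(n))
    df = pd.DataFrame(rows, columns=["al_category", "cisr_class", "cwp"])
    df["al_category"] = pd.Categorical(
        df["al_category"], categories=["low", "middle", "high"], ordered=True
    )
    df["cisr_class"] = pd.Categorical(
        df["cisr_class"], categories=["no_disorder", "common_mental_disorder"]
    )
    return df
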