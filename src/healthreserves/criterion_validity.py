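"""Criterion-validity analyses of the indicators and the overall measure.

Implements the analysis set used to validate the composite against later
self-rated health and 14-year all-cause mortality: bivariate cross-tabs with
chi-square tests, Kaplan-Meier survival with Greenwood confidence bands and
logrank tests, sex-adjusted logistic (odds ratios, 99% CI) and Cox
proportional-hazards models (hazard ratios, 99% CI, Efron tie handling) with
Schoenfeld-residual proportionality checks, and sensitivity/specificity with
Wilson 95% intervals.

Model numerics delegate to statsmodels (logistic) and lifelines (survival);
this module owns the estimate/CI extraction, reference-level handling and
report assembly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)


class SeparationError(RuntimeError):
    """The likelihood is degenerate (perfect separation / monotone likelihood)."""


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal half-up rounding, as used when printing percentages."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """Three-decimal p-value with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{round_half_up(p, 3):.3f}"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposed/case 2x2 layout.

    ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed non-cases,
    ``d`` unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells) or sum(cells) < 1:
            raise ValueError("cell counts must be nonnegative with total >= 1")

    @classmethod
    def from_booleans(
        cls, exposed: Sequence[bool], case: Sequence[bool]
    ) -> "ContingencyTable2x2":
        e = np.asarray(exposed, dtype=bool)
        k = np.asarray(case, dtype=bool)
        if e.shape != k.shape:
            raise ValueError("exposed and case must have equal length")
        return cls(
            a=int((e & k).sum()),
            b=int((~e & k).sum()),
            c=int((e & ~k).sum()),
            d=int((~e & ~k).sum()),
        )

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ValidationResult:
    """One effect estimate (or rate) with its confidence bounds."""

    exposure: str
    level: str
    outcome: str
    estimate_type: str  # OR | HR | Se | Spe | survival_probability
    point: float
    ci_low: float
    ci_high: float
    ci_level: float
    reference: str | None = None
    adjustment: tuple[str, ...] = ()
    n: int | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.ci_low) or self.ci_low <= self.point <= self.ci_high):
            raise ValueError("confidence bounds must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "level": self.level,
            "reference": self.reference,
            "outcome": self.outcome,
            "type": self.estimate_type,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "adjustment": "+".join(self.adjustment),
            "n": self.n,
            "p_value": self.p_value,
        }


def results_frame(results: Sequence[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def crude_odds_ratio(
    table: ContingencyTable2x2,
    ci_level: float = 0.99,
    exposure: str = "exposure",
    outcome: str = "outcome",
) -> ValidationResult:
    """Unadjusted odds ratio (a*d)/(b*c) with the Woolf log-normal interval.

    With a zero cell the point estimate is reported where defined and the
    interval is NaN (no continuity correction is applied).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        point = math.inf if a * d > 0 else math.nan
    else:
        point = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        lo = hi = math.nan
    else:
        z = stats.norm.ppf(0.5 + ci_level / 2)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = point * math.exp(-z * se), point * math.exp(z * se)
    return ValidationResult(
        exposure=exposure, level="exposed", outcome=outcome,
        estimate_type="OR", point=point, ci_low=lo, ci_high=hi,
        ci_level=ci_level, n=table.total,
    )


def _rate_result(
    k: int, n: int, which: str, ci_level: float, method: str,
    exposure: str, outcome: str,
) -> ValidationResult:
    if n == 0:
        return ValidationResult(
            exposure=exposure, level=which, outcome=outcome,
            estimate_type=which, point=math.nan, ci_low=math.nan,
            ci_high=math.nan, ci_level=ci_level, n=0,
        )
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method=method)
    return ValidationResult(
        exposure=exposure, level=which, outcome=outcome, estimate_type=which,
        point=k / n, ci_low=float(lo), ci_high=float(hi),
        ci_level=ci_level, n=n,
    )


def sens_spec(
    predicted_positive: Sequence[bool] | ContingencyTable2x2,
    condition_positive: Sequence[bool] | None = None,
    ci_level: float = 0.95,
    method: str = "wilson",
    exposure: str = "classifier",
    outcome: str = "condition",
) -> tuple[ValidationResult, ValidationResult]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    Accepts paired boolean sequences or a ``ContingencyTable2x2`` (exposed =
    predicted positive, case = condition positive).  Intervals are Wilson
    score by default (``method='normal'`` for the Wald comparison).  An
    undefined rate (no condition positives or negatives) is returned as NaN.
    """
    if isinstance(predicted_positive, ContingencyTable2x2):
        t = predicted_positive
    else:
        if condition_positive is None:
            raise ValueError("condition_positive required with boolean input")
        t = ContingencyTable2x2.from_booleans(predicted_positive, condition_positive)
    se = _rate_result(t.a, t.a + t.b, "Se", ci_level, method, exposure, outcome)
    spe = _rate_result(t.d, t.c + t.d, "Spe", ci_level, method, exposure, outcome)
    return se, spe


class KaplanMeierCurve:
    """Product-limit survival estimate with Greenwood CI on the log scale.

    The estimate itself comes from the lifelines fitter; the confidence band
    uses the Greenwood variance of log S(t):
    ``S(t) * exp(+/- z * sqrt(sum d_i / (n_i (n_i - d_i))))``.
    """

    def __init__(self, time_years: Sequence[float], event: Sequence[bool]):
        t = np.asarray(time_years, dtype=float)
        e = np.asarray(event, dtype=bool)
        if len(t) == 0:
            raise ValueError("at least one subject required")
        self._kmf = KaplanMeierFitter().fit(t, e)
        tbl = self._kmf.event_table
        d = tbl["observed"].to_numpy(dtype=float)
        n = tbl["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where((d > 0) & (n > d), d / (n * (n - d)), np.where(d >= n, np.nan, 0.0))
        self._times = tbl.index.to_numpy(dtype=float)
        self._var_log_s = np.cumsum(term)
        self._surv = self._kmf.survival_function_["KM_estimate"].to_numpy()

    def survival_at(self, t: float) -> float:
        return float(self._kmf.predict(t))

    def ci_at(self, t: float, ci_level: float = 0.95) -> tuple[float, float]:
        s = self.survival_at(t)
        idx = np.searchsorted(self._times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        v = self._var_log_s[idx]
        if not np.isfinite(v) or s == 0.0:
            return (0.0, s)
        z = stats.norm.ppf(0.5 + ci_level / 2)
        half = z * math.sqrt(v)
        return (min(1.0, s * math.exp(-half)), min(1.0, s * math.exp(half)))

    @property
    def event_table(self) -> pd.DataFrame:
        return self._kmf.event_table


def kaplan_meier(
    time_years: Sequence[float], event: Sequence[bool]
) -> KaplanMeierCurve:
    """Fit the product-limit estimator; see ``KaplanMeierCurve``."""
    return KaplanMeierCurve(time_years, event)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(
    time_years: Sequence[float],
    event: Sequence[bool],
    group_labels: Sequence,
) -> LogrankResult:
    """k-group logrank test; df = k - 1.  Requires >= 2 groups and >= 1 event."""
    g = pd.Series(group_labels)
    k = g.nunique()
    if k < 2:
        raise ValueError("logrank test requires at least two groups")
    if not np.asarray(event, dtype=bool).any():
        raise ValueError("logrank test requires at least one event")
    res = multivariate_logrank_test(
        np.asarray(time_years, dtype=float), g.to_numpy(),
        np.asarray(event, dtype=bool),
    )
    return LogrankResult(
        statistic=float(res.test_statistic), df=k - 1, p_value=float(res.p_value)
    )


def _exposure_design(
    exposure: pd.Series, reference=None
) -> tuple[pd.DataFrame, list[tuple[str, str]], str | None]:
    """Design columns for an exposure: dummies vs reference, or numeric as-is."""
    if pd.api.types.is_numeric_dtype(exposure) and not isinstance(
        exposure.dtype, pd.CategoricalDtype
    ) and exposure.dropna().nunique() > 2 and reference is None:
        name = str(exposure.name or "exposure")
        return exposure.astype(float).to_frame(name), [(name, name)], None
    s = exposure.astype(object)
    levels = list(pd.unique(s.dropna()))
    if isinstance(exposure.dtype, pd.CategoricalDtype):
        levels = [lv for lv in exposure.cat.categories if lv in set(levels)]
    else:
        # deterministic ordering; the smallest level is the default reference
        levels = sorted(levels, key=str)
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present in exposure")
    cols, meta = {}, []
    name = str(exposure.name or "exposure")
    for lv in levels:
        if lv == reference:
            continue
        col = f"{name}[{lv}]"
        cols[col] = (s == lv).astype(float)
        meta.append((col, str(lv)))
    return pd.DataFrame(cols, index=exposure.index), meta, str(reference)


def fit_logistic(
    outcome: Sequence[bool] | pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference=None,
    ci_level: float = 0.99,
) -> list[ValidationResult]:
    """Maximum-likelihood logistic regression; one OR per non-reference level.

    Binary (or two-level) exposures yield a single OR; a numeric exposure
    with more than two distinct values is entered linearly and the OR is per
    unit.  Wald intervals at ``ci_level``.  Perfect separation raises
    ``SeparationError`` rather than returning a silent estimate.
    """
    y = pd.Series(outcome).astype(float).reset_index(drop=True)
    exposure = exposure.reset_index(drop=True)
    design, meta, ref = _exposure_design(exposure, reference)
    X = design
    adjustment: tuple[str, ...] = ()
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        cov_num = pd.DataFrame(index=cov.index)
        for c in cov.columns:
            if pd.api.types.is_numeric_dtype(cov[c]) or pd.api.types.is_bool_dtype(cov[c]):
                cov_num[c] = cov[c].astype(float)
            else:
                dums = pd.get_dummies(cov[c], prefix=c, drop_first=True)
                cov_num = cov_num.join(dums.astype(float))
        X = X.join(cov_num)
        adjustment = tuple(covariates.columns)
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        RuntimeWarning,
        np.linalg.LinAlgError,
    ) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 30:
        raise SeparationError("logistic fit did not converge (separation likely)")
    conf = fit.conf_int(alpha=1 - ci_level)
    out = []
    for col, level in meta:
        out.append(
            ValidationResult(
                exposure=str(exposure.name or "exposure"), level=level,
                reference=ref, outcome=str(getattr(outcome, "name", "outcome") or "outcome"),
                estimate_type="OR", point=float(np.exp(fit.params[col])),
                ci_low=float(np.exp(conf.loc[col, 0])),
                ci_high=float(np.exp(conf.loc[col, 1])),
                ci_level=ci_level, adjustment=adjustment, n=int(len(y)),
                p_value=float(fit.pvalues[col]),
            )
        )
    return out


@dataclass
class CoxDiagnostics:
    """Schoenfeld proportional-hazards check per model term.

    ``ph_test`` holds the test statistic and p-value per covariate
    (rank-transformed time); ``scaled_schoenfeld`` carries the residuals
    indexed by event time for scatter inspection.
    """

    ph_test: pd.DataFrame
    scaled_schoenfeld: pd.DataFrame


def fit_cox(
    time_years: Sequence[float],
    event: Sequence[bool],
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference=None,
    ci_level: float = 0.99,
    ties: str = "efron",
) -> tuple[list[ValidationResult], CoxDiagnostics]:
    """Cox partial-likelihood fit; one HR per non-reference exposure level.

    Efron tie handling (the only scheme the backend implements).  Emits the
    Schoenfeld-residual proportionality test and the scaled residuals for
    visual inspection.  A level with no events (monotone likelihood) raises
    ``SeparationError``.
    """
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is available")
    t = pd.Series(np.asarray(time_years, dtype=float), name="time").reset_index(drop=True)
    e = pd.Series(np.asarray(event, dtype=bool), name="event").reset_index(drop=True)
    exposure = exposure.reset_index(drop=True)
    design, meta, ref = _exposure_design(exposure, reference)
    if not pd.api.types.is_numeric_dtype(exposure) or meta[0][0] != meta[0][1]:
        for lv in list(pd.unique(exposure.dropna())):
            if not e[(exposure == lv).to_numpy()].any():
                raise SeparationError(
                    f"exposure level {lv!r} has no events; HR inestimable"
                )
    adjustment: tuple[str, ...] = ()
    X = design
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        cov_num = pd.DataFrame(index=cov.index)
        for c in cov.columns:
            if pd.api.types.is_numeric_dtype(cov[c]) or pd.api.types.is_bool_dtype(cov[c]):
                cov_num[c] = cov[c].astype(float)
            else:
                cov_num = cov_num.join(
                    pd.get_dummies(cov[c], prefix=c, drop_first=True).astype(float)
                )
        X = X.join(cov_num)
        adjustment = tuple(covariates.columns)
    df = X.copy()
    df["time"] = t
    df["event"] = e.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError
        raise SeparationError(f"Cox fit failed: {exc}") from exc
    z = stats.norm.ppf(0.5 + ci_level / 2)
    results = []
    for col, level in meta:
        beta = float(cph.params_[col])
        se_b = float(cph.standard_errors_[col])
        results.append(
            ValidationResult(
                exposure=str(exposure.name or "exposure"), level=level,
                reference=ref, outcome="mortality", estimate_type="HR",
                point=math.exp(beta), ci_low=math.exp(beta - z * se_b),
                ci_high=math.exp(beta + z * se_b), ci_level=ci_level,
                adjustment=adjustment, n=int(len(t)),
                p_value=float(cph.summary.loc[col, "p"]),
            )
        )
    ph = proportional_hazard_test(cph, df, time_transform="rank")
    diag = CoxDiagnostics(
        ph_test=ph.summary,
        scaled_schoenfeld=cph.compute_residuals(df, "scaled_schoenfeld"),
    )
    return results, diag


# ---------------------------------------------------------------------------
# cohort-level orchestration

#: Positive classes used in the sensitivity/specificity block.
POSITIVE_CLASSES = {
    "al_category": ("middle", "high"),
    "cisr_class": ("common_mental_disorder",),
    "cwp": (True,),
    "category": ("medium", "impaired"),
}


def build_analysis_table(cohort, panel=None, cisr_cutoff: int = 9,
                         scheme=None, srh_column: str = "srh_46",
                         followup_years: float = 14.0):
    """Score a raw cohort table into the complete-case analysis table.

    Applies the SRH carry-back rule (when ``srh_column`` is the age-46
    item), derives the three reserve indicators and the overall measure,
    builds the survival outcome, and drops rows with any missing indicator
    or outcome.  Returns one row per analysable individual with columns
    ``sex, al_score, al_category, cisr_score, cisr_class, cwp, value,
    category, srh_poor, time_years, event, response_month``.
    """
    from . import outcomes as _outcomes
    from . import overall_health as _overall
    from . import reserve_indicators as _ri

    panel = _ri.DEFAULT_PANEL if panel is None else panel
    scheme = _overall.DEFAULT_GROUPING if scheme is None else scheme

    ind = _ri.score_cohort(cohort, panel=panel, cisr_cutoff=cisr_cutoff)
    ov = _overall.compose(ind, scheme=scheme)
    if srh_column == "srh_46":
        srh = _outcomes.carry_back_srh(
            cohort["srh_46"], cohort["srh_50"], cohort["srh_55"]
        )["srh_46_binary"]
    else:
        srh = cohort[srh_column]
    surv = _outcomes.build_survival(cohort["death_time_years"], followup_years)

    tab = pd.DataFrame(index=cohort.index)
    tab["sex"] = cohort["sex"]
    for c in ("al_score", "al_category", "cisr_score", "cisr_class", "cwp"):
        tab[c] = ind[c]
    tab["value"] = ov["value"]
    tab["category"] = ov["category"]
    tab["srh_poor"] = pd.Series(srh, index=cohort.index).map(
        {"good": False, "poor": True}
    )
    tab["time_years"] = surv["time_years"]
    tab["event"] = surv["event"]
    if "response_month" in cohort.columns:
        tab["response_month"] = cohort["response_month"]
    complete = tab[
        ["al_category", "cisr_class", "cwp", "value", "srh_poor", "time_years"]
    ].notna().all(axis=1)
    tab = tab[complete].copy()
    tab["srh_poor"] = tab["srh_poor"].astype(bool)
    tab["event"] = tab["event"].astype(bool)
    return tab


#: Exposure columns analysed in the report: (column, reference level).
REPORT_EXPOSURES = (
    ("al_category", "low"),
    ("cisr_class", "no_disorder"),
    ("cwp", False),
    ("category", None),  # reference = first grouping label
)


@dataclass
class ValidityReport:
    """The full criterion-validity analysis set for one cohort.

    ``bivariate_srh``: level-by-SRH counts/percentages with chi-square
    p-values; ``bivariate_mortality``: Kaplan-Meier survival at the window
    end with Greenwood 95% CI and logrank p-values; ``adjusted_estimates``:
    sex-adjusted ORs and HRs with 99% CI; ``sens_spec``: Se/Spe of each
    dichotomised indicator against both outcomes; ``ph_diagnostics``:
    Schoenfeld tests per Cox model.
    """

    n: int
    bivariate_srh: pd.DataFrame
    bivariate_mortality: pd.DataFrame
    adjusted_estimates: pd.DataFrame
    sens_spec: pd.DataFrame
    ph_diagnostics: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bivariate_srh.to_csv(out / "bivariate_srh.csv", index=False)
        self.bivariate_mortality.to_csv(out / "bivariate_mortality.csv", index=False)
        self.adjusted_estimates.to_csv(out / "adjusted_estimates.csv", index=False)
        self.sens_spec.to_csv(out / "sens_spec.csv", index=False)
        (out / "report.md").write_text(self.to_markdown())

    def to_markdown(self) -> str:
        parts = [f"# Criterion validity report (n = {self.n})\n"]
        for title, df in (
            ("Self-rated health bivariate", self.bivariate_srh),
            ("Mortality bivariate", self.bivariate_mortality),
            ("Sex-adjusted estimates (99% CI)", self.adjusted_estimates),
            ("Sensitivity / specificity (95% CI)", self.sens_spec),
        ):
            parts.append(f"## {title}\n\n{df.to_markdown(index=False)}\n")
        return "\n".join(parts)


def validity_report(analysis: pd.DataFrame, followup_years: float = 14.0,
                    ci_level: float = 0.99) -> ValidityReport:
    """Run the full criterion-validity analysis set on an analysis table."""
    n = len(analysis)
    exposures = []
    for col, ref in REPORT_EXPOSURES:
        if ref is None:
            cats = analysis[col].cat.categories if isinstance(
                analysis[col].dtype, pd.CategoricalDtype
            ) else pd.unique(analysis[col])
            ref = cats[0]
        exposures.append((col, ref))

    # bivariate: SRH cross-tabs with chi-square
    srh_rows = []
    for col, _ in exposures:
        ct = pd.crosstab(analysis[col], analysis["srh_poor"])
        chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
        for lvl in ct.index:
            good = int(ct.loc[lvl].get(False, 0))
            poor = int(ct.loc[lvl].get(True, 0))
            srh_rows.append({
                "indicator": col, "level": str(lvl),
                "n_good": good, "n_poor": poor,
                "pct_good": round_half_up(100 * good / max(ct[False].sum(), 1), 2)
                if False in ct.columns else float("nan"),
                "pct_poor": round_half_up(100 * poor / max(ct[True].sum(), 1), 2)
                if True in ct.columns else float("nan"),
                "chi2_p": format_p(p),
            })
    bivariate_srh = pd.DataFrame(srh_rows)

    # bivariate: KM survival at window end + logrank per indicator
    mort_rows = []
    for col, _ in exposures:
        lr = logrank_test(analysis["time_years"], analysis["event"], analysis[col])
        for lvl in (analysis[col].cat.categories if isinstance(
            analysis[col].dtype, pd.CategoricalDtype
        ) else pd.unique(analysis[col])):
            sub = analysis[analysis[col] == lvl]
            if not len(sub):
                continue
            km = kaplan_meier(sub["time_years"], sub["event"])
            s = km.survival_at(followup_years)
            lo, hi = km.ci_at(followup_years, 0.95)
            mort_rows.append({
                "indicator": col, "level": str(lvl), "n": len(sub),
                "survival_at_end": s, "ci_low": lo, "ci_high": hi,
                "logrank_p": format_p(lr.p_value),
            })
    bivariate_mortality = pd.DataFrame(mort_rows)

    # sex-adjusted OR (logistic) and HR (Cox), 99% CI
    est: list[ValidationResult] = []
    ph_diags = {}
    sexcov = analysis[["sex"]]
    for col, ref in exposures:
        exp_series = analysis[col]
        if isinstance(exp_series.dtype, pd.CategoricalDtype):
            exp_series = exp_series.cat.remove_unused_categories()
        ors = fit_logistic(
            analysis["srh_poor"].rename("srh_poor"), exp_series.rename(col),
            covariates=sexcov, reference=ref, ci_level=ci_level,
        )
        est.extend(ors)
        hrs, diag = fit_cox(
            analysis["time_years"], analysis["event"], exp_series.rename(col),
            covariates=sexcov, reference=ref, ci_level=ci_level,
        )
        est.extend(hrs)
        ph_diags[col] = diag
    adjusted = results_frame(est)

    # Se/Spe of each dichotomised indicator against both outcomes
    ss_rows = []
    for col, positives in POSITIVE_CLASSES.items():
        pred = analysis[col].isin(positives)
        for out_name, cond in (
            ("mortality", analysis["event"]),
            ("srh_poor", analysis["srh_poor"]),
        ):
            se, spe = sens_spec(pred, cond, exposure=col, outcome=out_name)
            ss_rows.append({
                "indicator": col,
                "positive_class": "/".join(str(p) for p in positives),
                "outcome": out_name,
                "Se": se.point, "Se_lo": se.ci_low, "Se_hi": se.ci_high,
                "Se_pct": round_half_up(100 * se.point) if not math.isnan(se.point) else float("nan"),
                "Spe": spe.point, "Spe_lo": spe.ci_low, "Spe_hi": spe.ci_high,
                "Spe_pct": round_half_up(100 * spe.point) if not math.isnan(spe.point) else float("nan"),
            })
    ss = pd.DataFrame(ss_rows)

    return ValidityReport(
        n=n, bivariate_srh=bivariate_srh, bivariate_mortality=bivariate_mortality,
        adjusted_estimates=adjusted, sens_spec=ss, ph_diagnostics=ph_diags,
    )
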