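"""Synthetic mid-life cohort generator.

Produces individual-level tables with the joint structure the downstream
analysis assumes: a latent frailty ``z ~ N(0,1)`` per person pushes every
biomarker toward its risk tail, inflates CIS-r symptom domains and pain
propensity, raises the odds of poor self-rated health and scales an
exponential mortality hazard.  Administrative censoring applies at the end
of the follow-up window; there is no loss to follow-up.

Randomness uses one root seed with a named substream per field family, so
adding a field family never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from collections import Counter

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    BIOMARKERS,
    CISR_DOMAINS,
    CISR_DOMAIN_MAX,
    PAIN_REGIONS,
    GeneratorConfig,
)
from .outcomes import carry_back_srh
from .reserve_indicators import RISK_DIRECTIONS

#: Column order of the generated cohort table.
COHORT_COLUMNS: tuple[str, ...] = (
    ("id", "sex")
    + BIOMARKERS
    + tuple(f"cisr_{d}" for d in CISR_DOMAINS)
    + ("pain_duration_3mo",)
    + tuple(f"pain_{r}" for r in PAIN_REGIONS)
    + ("srh_46", "srh_50", "srh_55", "death_time_years", "response_month",
       "pregnant", "blood_obtained", "frailty")
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: child generator keyed by (root seed, crc32(name))."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one cohort of ``config.n_individuals`` rows.

    Identical config (including seed) gives byte-identical output.  The
    latent frailty is returned in the ``frailty`` column — it is synthetic
    bookkeeping with no analogue in real survey data, kept for parameter
    recovery and coverage checks.
    """
    n = config.n_individuals
    seed = config.seed
    cal = config.calibration

    z = _rng(seed, "frailty").standard_normal(n)
    female = _rng(seed, "sex").random(n) < config.prop_female
    sex = np.where(female, "female", "male")

    df = pd.DataFrame({"id": np.arange(1, n + 1), "sex": sex})

    # biomarkers: u = lam * (signed z) + sqrt(1-lam^2) eps on a standard
    # scale, mapped to the measurement scale by sex, rounded to instrument
    # resolution.  The sign orients frailty toward the risk tail.
    for name in BIOMARKERS:
        params = config.biomarker_params[name]
        lam = config.latent_effects.biomarkers.get(name, 0.0)
        sign = 1.0 if RISK_DIRECTIONS[name] == "upper_quartile" else -1.0
        eps = _rng(seed, f"biomarker:{name}").standard_normal(n)
        u = sign * lam * z + np.sqrt(1.0 - lam**2) * eps
        loc = np.where(female, params.female_loc, params.male_loc)
        scale = np.where(female, params.female_scale, params.male_scale)
        v = loc + scale * u
        if params.lognormal:
            v = np.exp(v)
        df[name] = np.round(v / params.round_step) * params.round_step

    # CIS-r domains: shared per-person symptom propensity on the logit
    # scale; each domain ~ Binomial(max, p).
    p_sym = expit(cal.cisr_intercept + config.latent_effects.cisr * z)
    rng_cis = _rng(seed, "cisr")
    for d in CISR_DOMAINS:
        df[f"cisr_{d}"] = rng_cis.binomial(CISR_DOMAIN_MAX[d], p_sym)

    # pain: latent propensity q correlated with frailty; an any-pain gate,
    # then chronicity and five region summaries conditionally independent
    # given q.  No pain reported => duration and all regions false.
    lam_p = config.latent_effects.pain
    rng_pain = _rng(seed, "pain")
    q = lam_p * z + np.sqrt(1.0 - lam_p**2) * rng_pain.standard_normal(n)
    any_pain = rng_pain.random(n) < expit(
        cal.pain_report_intercept + cal.pain_report_slope * q
    )
    df["pain_duration_3mo"] = any_pain & (
        rng_pain.random(n)
        < expit(cal.pain_duration_intercept + cal.pain_duration_slope * q)
    )
    p_region = expit(cal.pain_region_intercept + cal.pain_region_slope * q)
    for r in PAIN_REGIONS:
        df[f"pain_{r}"] = any_pain & (rng_pain.random(n) < p_region)

    # self-rated health at three ages: logistic in frailty, independent
    # draws given z (the carry-back rule needs concordance to be imperfect).
    p_poor = expit(cal.srh_intercept + config.outcome_effects.srh_log_or * z)
    rng_srh = _rng(seed, "srh")
    for age in (46, 50, 55):
        df[f"srh_{age}"] = np.where(rng_srh.random(n) < p_poor, "poor", "good")

    # mortality: exponential hazard scaled by exp(log-HR * z); deaths beyond
    # the window are administratively censored (recorded as absent).
    rate = config.baseline_hazard * np.exp(
        config.outcome_effects.mortality_log_hr * z
    )
    t = _rng(seed, "mortality").exponential(1.0 / rate)
    df["death_time_years"] = np.where(t <= config.followup_years, t, np.nan)

    df["response_month"] = _rng(seed, "month").integers(1, 13, size=n)

    # exclusion mechanisms
    rates = config.exclusion_rates
    rng_ex = _rng(seed, "exclusions")
    df["pregnant"] = female & (rng_ex.random(n) < rates.pregnancy)
    df["blood_obtained"] = rng_ex.random(n) >= rates.no_blood
    miss_bio = rng_ex.random(n) < rates.missing_biomarker
    which = rng_ex.integers(0, len(BIOMARKERS), size=n)
    for j, name in enumerate(BIOMARKERS):
        df.loc[miss_bio & (which == j), name] = np.nan
    df.loc[rng_ex.random(n) < rates.missing_srh, "srh_46"] = np.nan

    df["frailty"] = z
    return df[list(COHORT_COLUMNS)]


def apply_exclusions(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, Counter[str]]:
    """Drop records the survey's selection rules exclude.

    In order: pregnant women; records without blood; records with a missing
    reserve-indicator field (any biomarker, CIS-r domain or pain field);
    records with a missing outcome (self-rated health unrecoverable by the
    carry-back rule — vital status is never missing here).  Returns the
    complete-case table and a log counting each exclusion reason.
    """
    log: Counter[str] = Counter()
    df = records
    if df.empty:
        return df.copy(), log

    pregnant = df["pregnant"].astype(bool)
    log["pregnant"] = int(pregnant.sum())
    df = df[~pregnant]

    no_blood = ~df["blood_obtained"].astype(bool)
    log["no_blood"] = int(no_blood.sum())
    df = df[~no_blood]

    indicator_cols = (
        list(BIOMARKERS)
        + [f"cisr_{d}" for d in CISR_DOMAINS]
        + ["pain_duration_3mo"]
        + [f"pain_{r}" for r in PAIN_REGIONS]
    )
    miss_ind = df[indicator_cols].isna().any(axis=1)
    log["missing_indicator"] = int(miss_ind.sum())
    df = df[~miss_ind]

    srh = carry_back_srh(df["srh_46"], df["srh_50"], df["srh_55"])
    miss_out = srh["srh_46_binary"].isna()
    log["missing_outcome"] = int(miss_out.sum())
    df = df[~miss_out]

    return df.copy(), log
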