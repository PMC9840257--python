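"""Configuration models for the synthetic cohort generator.

The generator emulates the structure of a mid-life biomedical survey wave of
a British birth cohort: one row per participant carrying sex, 14 continuous
biomarkers spanning four physiological systems, 14 psychiatric symptom-domain
scores (abbreviated CIS-r), a pain report (duration flag plus five body-region
summaries), self-rated health at three ages, vital status over a 14-year
follow-up window, the survey response month and exclusion flags.

A single latent frailty factor ``z ~ N(0, 1)`` per individual induces the
joint structure: it shifts each biomarker toward its risk direction, inflates
symptom-domain intensity and pain propensity, raises the odds of poor
self-rated health and scales the mortality hazard.  Setting all loadings to
zero yields mutually independent indicators and outcomes.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: The 14 CIS-r symptom domains.  Thirteen are scored 0-4; suicidal ideation
#: is scored 0-5.
CISR_DOMAINS: tuple[str, ...] = (
    "somatic_symptoms",
    "fatigue",
    "concentration",
    "forgetfulness",
    "sleep_problems",
    "irritability",
    "physical_health_worry",
    "depression",
    "depressive_ideas",
    "suicidal_ideation",
    "anxiety",
    "phobias",
    "panic",
    "worry",
)

CISR_DOMAIN_MAX: dict[str, int] = {d: 4 for d in CISR_DOMAINS}
CISR_DOMAIN_MAX["suicidal_ideation"] = 5

#: Five body-region summaries of the pain manikin used by the chronic
#: widespread pain classification.
PAIN_REGIONS: tuple[str, ...] = (
    "above_waist",
    "below_waist",
    "left_side",
    "right_side",
    "axial",
)


class BiomarkerParams(BaseModel):
    """Location/scale of one biomarker by sex, on its measurement scale.

    ``lognormal`` biomarkers (right-skewed analytes such as CRP, IgE and
    triglycerides) take location/scale on the natural-log scale and are
    exponentiated.  ``round_step`` mimics instrument resolution (integer
    mmHg for blood pressure, 0.1% HbA1c units, ...), which produces the
    tied values real assay data carry.
    """

    model_config = ConfigDict(frozen=True)

    male_loc: float
    male_scale: float = Field(gt=0)
    female_loc: float
    female_scale: float = Field(gt=0)
    round_step: float = Field(default=0.01, gt=0)
    lognormal: bool = False


def _default_biomarker_params() -> dict[str, BiomarkerParams]:
    def p(ml, ms, fl, fs, step=0.01, log=False):
        return BiomarkerParams(
            male_loc=ml, male_scale=ms, female_loc=fl, female_scale=fs,
            round_step=step, lognormal=log,
        )

    return {
        # neuroendocrine (salivary cortisol, nmol/L; t1-t2 = diurnal decline)
        "cortisol_t1": p(16.0, 6.0, 15.0, 6.0, 0.1),
        "cortisol_t1_t2": p(8.0, 5.0, 7.5, 5.0, 0.1),
        # immune / inflammatory
        "igf1": p(28.0, 9.0, 26.0, 9.0, 1.0),          # nmol/L
        "crp": p(0.0, 1.1, 0.1, 1.1, 0.01, log=True),  # mg/L, log scale
        "fibrinogen": p(2.8, 0.6, 3.0, 0.6, 0.01),     # g/L
        "ige": p(3.5, 1.4, 3.2, 1.4, 1.0, log=True),   # kU/L, log scale
        # metabolic
        "hdl": p(1.4, 0.35, 1.7, 0.4, 0.01),           # mmol/L
        "ldl": p(3.7, 0.9, 3.5, 0.9, 0.01),
        "triglycerides": p(0.5, 0.55, 0.2, 0.5, 0.01, log=True),
        "hba1c": p(5.3, 0.6, 5.3, 0.55, 0.1),          # %
        # cardiovascular / respiratory
        "sbp": p(130.0, 14.0, 122.0, 15.0, 1.0),       # mmHg
        "dbp": p(80.0, 10.0, 76.0, 10.0, 1.0),
        "heart_rate": p(70.0, 10.0, 74.0, 10.0, 1.0),  # bpm
        "peak_flow": p(560.0, 90.0, 410.0, 75.0, 10.0),  # L/min
    }


BIOMARKERS: tuple[str, ...] = tuple(_default_biomarker_params())


class LatentEffects(BaseModel):
    """Loadings of the latent frailty on each observed family.

    ``biomarkers`` maps marker name to a correlation-scale loading in
    [-1, 1]; the sign convention is handled downstream (frailty always pushes
    toward the risk direction of the marker).  ``cisr`` and ``pain`` act on
    the logit scale of domain-symptom intensity and pain propensity.
    """

    biomarkers: dict[str, float] = Field(
        default_factory=lambda: {b: 0.25 for b in BIOMARKERS}
    )
    cisr: float = 0.9
    pain: float = 0.55

    @model_validator(mode="after")
    def _check_loadings(self) -> "LatentEffects":
        for name, lam in self.biomarkers.items():
            if not -1.0 <= lam <= 1.0:
                raise ValueError(
                    f"biomarker loading for {name!r} must lie in [-1, 1]"
                )
        if not -1.0 <= self.pain <= 1.0:
            raise ValueError("pain loading must lie in [-1, 1]")
        return self

    @classmethod
    def null(cls) -> "LatentEffects":
        """All loadings zero: indicators independent of frailty."""
        return cls(biomarkers={b: 0.0 for b in BIOMARKERS}, cisr=0.0, pain=0.0)


class OutcomeEffects(BaseModel):
    """Effect of frailty on the two criterion outcomes.

    ``srh_log_or``: log odds-ratio per frailty SD for fair/poor/very-poor
    self-rated health.  ``mortality_log_hr``: log hazard-ratio per frailty SD
    for all-cause death.
    """

    srh_log_or: float = 1.0
    mortality_log_hr: float = math.log(2.0)

    @classmethod
    def null(cls) -> "OutcomeEffects":
        return cls(srh_log_or=0.0, mortality_log_hr=0.0)


class ExclusionRates(BaseModel):
    """Rates of the sample-selection mechanisms the survey applies."""

    pregnancy: float = Field(default=0.02, ge=0, le=1)   # among women
    no_blood: float = Field(default=0.05, ge=0, le=1)
    missing_biomarker: float = Field(default=0.02, ge=0, le=1)
    missing_srh: float = Field(default=0.06, ge=0, le=1)  # age-46 item

    @classmethod
    def null(cls) -> "ExclusionRates":
        return cls(pregnancy=0.0, no_blood=0.0, missing_biomarker=0.0,
                   missing_srh=0.0)


class Calibration(BaseModel):
    """Intercepts/slopes fixed so default marginals match the cohort wave.

    Calibrated once by simulation at n = 600,000 against the survey's
    printed marginal frequencies (~28% chronic widespread pain, ~11% CIS-r
    cases, ~23% high allostatic load, ~21.5% poor self-rated health,
    ~2.8% deaths over 14 years).
    """

    cisr_intercept: float = -2.94
    pain_report_intercept: float = 0.6
    pain_report_slope: float = 1.5
    pain_duration_intercept: float = 1.0
    pain_duration_slope: float = 1.5
    pain_region_intercept: float = 1.137
    pain_region_slope: float = 2.5
    srh_intercept: float = -1.541


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic cohort draw.

    Identical config (including ``seed``) yields byte-identical output.
    """

    n_individuals: int = Field(gt=0)
    seed: int = 0
    prop_female: float = Field(default=0.5126, ge=0, le=1)
    biomarker_params: dict[str, BiomarkerParams] = Field(
        default_factory=_default_biomarker_params
    )
    latent_effects: LatentEffects = Field(default_factory=LatentEffects)
    outcome_effects: OutcomeEffects = Field(default_factory=OutcomeEffects)
    exclusion_rates: ExclusionRates = Field(default_factory=ExclusionRates)
    calibration: Calibration = Field(default_factory=Calibration)
    baseline_hazard: float = Field(default=1.634e-3, gt=0)  # events / person-year
    followup_years: float = Field(default=14.0, gt=0)

    @model_validator(mode="after")
    def _check_panel(self) -> "GeneratorConfig":
        missing = set(BIOMARKERS) - set(self.biomarker_params)
        if missing:
            raise ValueError(
                f"biomarker_params missing entries for {sorted(missing)}"
            )
        return self
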