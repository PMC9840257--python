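# Methods notes

## The composite and its conventions

The overall health measure is a deliberately simple equal-weight sum.  Two
numerical conventions matter:

* **Quartile dichotomisation.**  Biomarker risk flags use the
  linear-interpolation sample quantile (p = 0.25/0.75) computed *within
  sex*, with strict inequality: a reading exactly at the boundary is coded
  low risk.  This is conservative and reproducible; with heavily tied data
  (rounded blood pressure, HbA1c) it flags somewhat fewer than 25% per
  marker.  Risk directions default to the usual allostatic-load
  conventions — upper tail for cortisol t1, CRP, fibrinogen, IgE, LDL,
  triglycerides, HbA1c, SBP, DBP and heart rate; lower tail for IGF-1, HDL,
  peak expiratory flow, and for the cortisol diurnal decline t1–t2 (a
  blunted decline is the risk state).  The cited AL literature varies on
  both points, so panel and directions are configurable.
* **CIS-r cutoff.**  "Cutoff 9" is read inclusively (score ≥ 9 is a case)
  and exposed as a parameter.  The abbreviated instrument's domain
  structure is carried as 14 domains, thirteen scored 0–4 and suicidal
  ideation 0–5; the score is the plain sum and no upper cap is imposed.

Composite values are exact half-units internally (integers on a doubled
scale; rationals in `recompose`), so grouping boundaries like 0.5 vs 1 never
depend on floating-point rounding.  Missing components make an individual
unscorable rather than being imputed, matching the complete-case design of
the analysis.

The alternative grouping merges the two lowest values
({0, 0.5} / {1} / {1.5–3}) and labels the merged class `optimal_merged`;
other published recompositions of the measure are hosted by the generic
`recompose` hook (ordinal components rescaled to [0, 1], user-supplied
interval grouping) rather than re-implemented, since their exact variable
definitions are not available.

## Statistical machinery

Logistic fits use statsmodels maximum likelihood with Wald intervals
(default 99%); a two-level exposure therefore reproduces the closed-form
crude OR exactly.  Cox fits use lifelines' partial likelihood with Efron tie
handling (the only scheme that backend implements) and emit the
Schoenfeld-residual proportionality test (rank-transformed time) plus the
scaled residuals for visual checks.  Kaplan–Meier point estimates come from
lifelines; the confidence band is Greenwood variance on the log-survival
scale, `S·exp(±z·√Σ d/(n(n−d)))`.  Crude odds ratios use the Woolf
log-normal interval with no continuity correction (a zero cell flags the
interval unavailable).  Sensitivity/specificity intervals are Wilson score
by default (the normal approximation is available for comparison), and
printed percentages round half-up.  Chi-square tests on r×c cross-tabs are
uncorrected; p-values print at three decimals with a `<0.001` floor.
Degenerate fits (perfect separation, an exposure level without events)
raise a `SeparationError` rather than returning a silent estimate.

## The synthetic cohort generator

One latent frailty `z ~ N(0,1)` per individual induces all cross-variable
structure:

* **Biomarkers** are Gaussian on a standard scale,
  `u = s·λ·z + √(1−λ²)·ε`, where the sign `s` orients frailty toward the
  marker's risk tail; right-skewed analytes (CRP, IgE, triglycerides) are
  exponentiated.  Values are mapped to sex-specific location/scale on
  plausible measurement scales and rounded to instrument resolution, which
  reproduces the tied values real assay data carry.  Default loading
  λ = 0.25 per marker.
* **CIS-r domains** are Binomial(domain max, p) with a shared per-person
  symptom propensity `p = expit(−2.94 + 0.9·z)`.
* **Pain** uses a latent propensity `q` (loading 0.55): an any-pain gate,
  then the chronicity flag and five conditionally independent region
  summaries, all logistic in `q`.  Painless individuals report no regions.
* **Outcomes.**  Poor self-rated health is logistic in `z` (default log-OR
  1.0 per SD, intercept −1.541), drawn independently at ages 46/50/55 given
  `z` so later-age concordance is imperfect and the carry-back rule has
  work to do.  Death times are exponential with hazard
  `1.634×10⁻³·exp(log 2 · z)` per person-year; censoring is administrative
  at the end of the 14-year window only (no loss to follow-up, matching a
  design that classifies anyone with later contact as alive).
* **Exclusion mechanisms** (pregnancy among women 2%, no blood 5%, a
  missing biomarker 2%, missing age-46 SRH 6%) are independent of frailty;
  defaults give roughly one in eight records excluded.

Intercepts and the baseline hazard were calibrated once by simulation at
n = 600,000 against the target sample's printed marginals (~28% CWP, ~11%
CIS-r cases, ~23% high AL, ~21.5% poor SRH, ~2.8% deaths/14 y) and then
frozen.  One limitation is structural: with sex-specific quartile cuts every
risk flag has ≈25% prevalence, forcing a mean AL score near 3.5, so an
equicorrelated single-factor model cannot reproduce the strongly low-shifted
AL category split observed in the real sample (44.9/32.2/22.9) — that split
implies tie-deflated flag rates well below 25%.  The default calibration
lands at roughly 35/38/27 with the high category inside a ±5-point band of
the real value; the low/middle split is not matched and is not asserted.

Randomness derives from one root seed through named substreams per field
family (frailty, sex, each biomarker, CIS-r, pain, SRH, mortality, month,
exclusions), so adding a family never perturbs another and identical configs
are byte-identical.

### What passing tests do and do not show

The generator shares the analysis' own model family (logistic SRH,
proportional-hazards mortality, single frailty factor), so parameter
recovery and CI coverage on it validate the estimation machinery, not the
measure's behaviour under model misspecification.  Real cohort features it
does not emulate: multi-factor correlation structure within and across
physiological systems, frailty-dependent attrition and item missingness,
age trends, calendar effects in the response month, and measurement error
correlated with health.  Negative-control and null-effect checks therefore
test internal consistency under exchangeability, not robustness to those
mechanisms.

## Problem sizes in the test and acceptance suites

Exact fixtures (published table counts) run at full printed size
(n = 7,043 expanded individuals).  Stochastic checks use n = 20,000 single
cohorts for marginal calibration, null association (|log OR| < 0.1) and
parameter recovery (±0.1 on log-OR 1.0; ±0.15 on log-HR log 2); interval
coverage uses 500 replicates at n = 2,000 (97–100% band for nominal 99%);
the negative-control agreement check uses 60 replicates at n = 3,000.
These sizes keep Monte-Carlo error a few times smaller than each tolerance.

## Known limitations

* AL category proportions beyond the high band are not calibrated (see
  above); only ranks of biomarkers matter downstream, so marginal
  distribution families were chosen for plausibility, not fitted.
* The joint indicator distribution is induced solely by the single frailty
  factor; the 12-cell cross-classification is matched in direction, not
  cell by cell.
* Cox tie handling is Efron-only; Breslow/exact are not available in the
  backend.
* Calendar-date inputs are reduced to durations immediately; no
  cause-specific mortality or competing risks.
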