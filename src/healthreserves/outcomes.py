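"""Criterion outcomes: dichotomised self-rated health and 14-year mortality.

Self-rated health (SRH) is the single general-health item, collapsed to
good (excellent/good) versus poor (fair/poor/very poor).  A missing age-46
response is recovered when the age-50 and age-55 responses agree (the
carry-back rule); discordant or incomplete later responses leave it missing.
Mortality follow-up runs from the biomedical survey to death or to
administrative censoring at the window boundary; individuals without a death
record are classified alive.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

#: Raw five-level SRH responses and their dichotomy.
SRH_LEVELS: dict[str, str] = {
    "excellent": "good",
    "good": "good",
    "fair": "poor",
    "poor": "poor",
    "very poor": "poor",
}


def dichotomize_srh(raw_srh: str | Sequence[str] | pd.Series) -> str | pd.Series:
    """Collapse 5-level responses to good/poor.

    Accepts a scalar or a sequence; missing values stay missing.  An
    unknown level raises ``ValueError``.
    """
    if isinstance(raw_srh, str):
        try:
            return SRH_LEVELS[raw_srh]
        except KeyError:
            raise ValueError(f"unknown self-rated health level {raw_srh!r}") from None
    s = pd.Series(raw_srh)
    ok = s.dropna()
    unknown = set(ok.unique()) - set(SRH_LEVELS)
    if unknown:
        raise ValueError(f"unknown self-rated health levels {sorted(unknown)}")
    return s.map(SRH_LEVELS)


def carry_back_srh(
    srh_46: Sequence[str] | pd.Series,
    srh_50: Sequence[str] | pd.Series,
    srh_55: Sequence[str] | pd.Series,
) -> pd.DataFrame:
    """Recover missing age-46 SRH from concordant age-50/55 responses.

    Inputs are already-dichotomised good/poor values (missing as NaN/None).
    A present age-46 value passes through untouched.  When it is missing and
    the two later responses agree, that value is carried back and flagged
    ``imputed``; otherwise the outcome stays missing and the individual is
    excluded downstream.

    Returns a frame with ``srh_46_binary`` (good/poor/NaN) and ``imputed``.
    """
    a = pd.Series(srh_46).reset_index(drop=True)
    b = pd.Series(srh_50).reset_index(drop=True)
    c = pd.Series(srh_55).reset_index(drop=True)
    for s in (a, b, c):
        bad = set(s.dropna().unique()) - {"good", "poor"}
        if bad:
            raise ValueError(
                f"carry_back_srh expects dichotomised values, got {sorted(bad)}"
            )
    concordant = a.isna() & b.notna() & (b == c)
    out = pd.DataFrame(
        {
            "srh_46_binary": np.where(a.notna(), a, np.where(concordant, b, None)),
            "imputed": concordant.to_numpy(),
        }
    )
    if isinstance(srh_46, pd.Series):
        out.index = srh_46.index
    return out


def build_survival(
    death_time: float | Sequence[float] | pd.Series | None,
    window_years: float = 14.0,
) -> pd.DataFrame:
    """Follow-up time and event indicator over the observation window.

    A death within the window yields ``(death_time, event=True)``; no death
    record, or a death beyond the window, yields administrative censoring at
    ``(window_years, event=False)``.  Negative death times are invalid.
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    t = pd.Series(
        [death_time] if np.isscalar(death_time) or death_time is None else death_time,
        dtype=float,
    )
    neg = t.dropna()
    if (neg < 0).any():
        raise ValueError("death times must be nonnegative")
    event = t.notna() & (t <= window_years)
    return pd.DataFrame(
        {
            "time_years": np.where(event, t, window_years),
            "event": event.to_numpy(),
        },
        index=t.index,
    )
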