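"""Weather aggregation, the De Martonne aridity index and percent-of-reference
arithmetic.

The De Martonne index I_DM = RR / (TM + 10) combines annual precipitation RR
(mm) with annual mean air temperature TM (degrees C); values below 20 indicate
semi-dry to dry conditions, values from 20 up to 30 a humid to Mediterranean
habitat, and 30 or more humid conditions.  Daily weather is carried as a
pandas DataFrame with columns ``date``, ``precip_mm``, ``tmean_C``,
``tmax_C`` (one row per day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AridityResult",
    "de_martonne",
    "classify_aridity",
    "aggregate",
    "percent_of_reference",
    "derive_reference",
    "aridity_summary",
    "WEATHER_COLUMNS",
    "HOT_DAY_THRESHOLD_C",
]

WEATHER_COLUMNS = ("date", "precip_mm", "tmean_C", "tmax_C")
#: Daily maximum temperature above which a day counts as hot (strict).
HOT_DAY_THRESHOLD_C = 25.0


@dataclass(frozen=True)
class AridityResult:
    I_DM: float
    aridity_class: str


def de_martonne(RR: float, TM: float) -> float:
    """De Martonne aridity index RR / (TM + 10).

    Parameters are annual precipitation in mm and annual mean air
    temperature in degrees C; the index is singular at TM = -10.
    """
    if TM <= -10.0:
        raise ValueError("mean temperature must exceed -10 degrees C")
    return RR / (TM + 10.0)


def classify_aridity(I_DM: float) -> str:
    """Aridity class label for an index value (boundaries closed below)."""
    if I_DM < 0:
        raise ValueError("aridity index must be non-negative")
    if I_DM < 20:
        return "semi-dry to dry"
    if I_DM < 30:
        return "humid to Mediterranean"
    return "humid"


def _window_dates(weather: pd.DataFrame, window: str) -> pd.DatetimeIndex:
    dates = pd.to_datetime(weather["date"])
    years = dates.dt.year.unique()
    if len(years) != 1:
        raise ValueError(f"weather table spans multiple years: {sorted(years)}")
    year = int(years[0])
    if window == "annual":
        return pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    if window == "jja":
        return pd.date_range(f"{year}-06-01", f"{year}-08-31", freq="D")
    raise ValueError(f"unknown window {window!r}; expected 'annual' or 'jja'")


def aggregate(weather: pd.DataFrame, window: str = "annual"):
    """Precipitation sum (mm), mean temperature (C) and hot-day count over a
    window ('annual' or 'jja' = June 1 to August 31).

    A hot day has tmax strictly above 25 C.  Missing days inside the window
    raise an error listing the gaps.
    """
    dates = pd.to_datetime(weather["date"])
    wanted = _window_dates(weather, window)
    present = pd.DatetimeIndex(dates.unique())
    missing = wanted.difference(present)
    if len(missing):
        shown = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise ValueError(f"missing days in {window} window: {shown}{more}")
    sel = weather.loc[dates.isin(wanted)]
    precip_sum = float(sel["precip_mm"].sum())
    tmean_avg = float(sel["tmean_C"].mean())
    hot_days = int((sel["tmax_C"] > HOT_DAY_THRESHOLD_C).sum())
    return precip_sum, tmean_avg, hot_days


def percent_of_reference(value: float, reference: float) -> float:
    """100 * value / reference (report alongside the integer-rounded form)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * value / reference


def derive_reference(value: float, pct: float) -> float:
    """Reference mean implied by a (value, percent-of-reference) pair."""
    if pct <= 0:
        raise ValueError("percentage must be positive")
    return value / (pct / 100.0)


def aridity_summary(weather: pd.DataFrame) -> AridityResult:
    """Annual De Martonne index and class from a one-year daily table."""
    rr, tm, _ = aggregate(weather, "annual")
    idm = de_martonne(rr, tm)
    return AridityResult(I_DM=idm, aridity_class=classify_aridity(idm))
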