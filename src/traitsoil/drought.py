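"""Extreme-drought design from daily rainfall via the Gumbel distribution.

The drought treatment length is set to the T-year return level of an annual
extreme statistic — by default the longest May-August run of days with less
than 1 mm of rain.  Annual maxima of such block statistics are classical
Gumbel territory: fit location mu and scale beta (maximum likelihood by
default; method-of-moments for very short records) and invert the CDF,

    x_T = mu - beta * ln(-ln(1 - 1/T)),

for the event expected once in T years.  The design length is rounded up to
whole days for shelter scheduling.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import gumbel_r

EULER_GAMMA = 0.5772156649015329

#: default seasonal window (month-day bounds, inclusive)
DEFAULT_WINDOW = ("05-01", "08-31")
#: a day with less rain than this is part of a dry spell
DEFAULT_WET_THRESHOLD_MM = 1.0


def _longest_run(dry: np.ndarray) -> int:
    best = cur = 0
    for d in dry:
        cur = cur + 1 if d else 0
        best = max(best, cur)
    return best


def annual_max_dry_spell(series: pd.DataFrame,
                         window: tuple[str, str] = DEFAULT_WINDOW,
                         wet_threshold_mm: float = DEFAULT_WET_THRESHOLD_MM,
                         ) -> pd.Series:
    """Longest dry spell (days with rain < threshold) per year in a window.

    ``series`` has columns ``date`` (parseable to datetime) and ``rain_mm``.
    Returns a Series indexed by year.
    """
    if not {"date", "rain_mm"}.issubset(series.columns):
        raise ValueError("rainfall series needs 'date' and 'rain_mm' columns")
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in rainfall series")
    if (df["rain_mm"] < 0).any():
        raise ValueError("negative rainfall")
    df = df.sort_values("date")
    start, end = window
    mmdd = df["date"].dt.strftime("%m-%d")
    in_window = (mmdd >= start) & (mmdd <= end)
    df = df[in_window]
    if df.empty:
        raise ValueError("empty seasonal window")
    out = {}
    for year, grp in df.groupby(df["date"].dt.year):
        dry = (grp["rain_mm"] < wet_threshold_mm).to_numpy()
        out[int(year)] = _longest_run(dry)
    return pd.Series(out, name="max_dry_spell_days").sort_index()


@dataclass
class GumbelFit:
    mu: float
    beta: float
    n_extremes: int
    method: str  # "MLE" or "moments"

    def to_dict(self) -> dict:
        return asdict(self)


def fit_gumbel(extremes, method: str = "MLE") -> GumbelFit:
    """Fit Gumbel (mu, beta) to a sample of annual extremes.

    MLE uses the standard right-skewed Gumbel likelihood; the moments
    fallback is beta = s*sqrt(6)/pi, mu = mean - gamma*beta (Euler gamma),
    preferred only for very short records.
    """
    x = np.asarray(extremes, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 extremes to fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all extremes equal")
    if method.upper() == "MLE":
        mu, beta = gumbel_r.fit(x)
    elif method.lower() == "moments":
        beta = x.std(ddof=1) * math.sqrt(6.0) / math.pi
        mu = x.mean() - EULER_GAMMA * beta
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return GumbelFit(mu=float(mu), beta=float(beta), n_extremes=int(x.size),
                     method=method.upper() if method.upper() == "MLE" else "moments")


def return_level(fit: GumbelFit, t_years: float) -> float:
    """Magnitude exceeded once in T years: mu - beta*ln(-ln(1 - 1/T))."""
    if t_years <= 1:
        raise ValueError("return period must exceed 1 year")
    return fit.mu - fit.beta * math.log(-math.log(1.0 - 1.0 / t_years))


def design_drought(series: pd.DataFrame, t_years: float = 100.0,
                   window: tuple[str, str] = DEFAULT_WINDOW,
                   wet_threshold_mm: float = DEFAULT_WET_THRESHOLD_MM,
                   method: str = "MLE") -> dict:
    """End-to-end drought design report from a daily rainfall series."""
    extremes = annual_max_dry_spell(series, window=window,
                                    wet_threshold_mm=wet_threshold_mm)
    fit = fit_gumbel(extremes.to_numpy(), method=method)
    level = return_level(fit, t_years)
    return {
        **fit.to_dict(),
        "T": t_years,
        "return_level": level,
        "return_level_days": int(math.ceil(level)),
        "window": list(window),
        "wet_threshold_mm": wet_threshold_mm,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
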