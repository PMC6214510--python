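"""Time-series and cross-tabulation analytics.

Daily article volume (UTC calendar days, zero-filled), ordinary
least-squares linear time trend, per-year mean/SD of daily counts, weekday
profiles, and the geography x subject crosstab.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import NewsArticle


@dataclass(frozen=True)
class DailySeries:
    """Zero-filled daily article counts over an inclusive date window."""

    start_date: _dt.date
    end_date: _dt.date
    counts: np.ndarray  # one nonnegative int per calendar day

    def __post_init__(self) -> None:
        span = (self.end_date - self.start_date).days + 1
        if len(self.counts) != span:
            raise ValueError(f"counts length {len(self.counts)} != day span {span}")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "count": self.counts})


@dataclass(frozen=True)
class YearStats:
    year: int
    mean: float
    sd: Optional[float]  # None when the year has < 2 days in the window
    n_days: int
    partial: bool  # the window does not cover the full calendar year


@dataclass(frozen=True)
class TrendFit:
    """OLS line through the daily series plus per-year summaries."""

    slope: float       # articles/day per day
    intercept: float   # articles/day at the series start
    yearly: tuple[YearStats, ...]


def daily_counts(
    articles: Sequence[NewsArticle], start: _dt.date, end: _dt.date
) -> DailySeries:
    """Count articles per UTC calendar day; out-of-window articles excluded."""
    if start > end:
        raise ValueError(f"inverted date range {start}..{end}")
    span = (end - start).days + 1
    counts = np.zeros(span, dtype=int)
    for art in articles:
        d = art.published_at
        if start <= d <= end:
            counts[(d - start).days] += 1
    return DailySeries(start_date=start, end_date=end, counts=counts)


def fit_trend(series: DailySeries) -> TrendFit:
    """OLS of daily count on day index, plus per-year mean/SD (ddof=1)."""
    y = np.asarray(series.counts, dtype=float)
    if y.size < 2:
        raise ValueError("trend fit requires >= 2 days")
    t = np.arange(y.size, dtype=float)
    fit = sm.OLS(y, sm.add_constant(t)).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])

    frame = series.to_frame()
    frame["year"] = frame["date"].dt.year
    yearly = []
    for year, grp in frame.groupby("year"):
        vals = grp["count"].to_numpy(dtype=float)
        full_year_days = (_dt.date(year, 12, 31) - _dt.date(year, 1, 1)).days + 1
        yearly.append(YearStats(
            year=int(year),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size >= 2 else None,
            n_days=int(vals.size),
            partial=vals.size < full_year_days,
        ))
    return TrendFit(slope=slope, intercept=intercept, yearly=tuple(yearly))


def weekday_profile(series: DailySeries) -> np.ndarray:
    """Mean daily count per weekday, Monday-first. Requires >= 7 days."""
    if len(series.counts) < 7:
        raise ValueError("weekday profile requires >= 7 days")
    frame = series.to_frame()
    frame["weekday"] = frame["date"].dt.dayofweek
    return frame.groupby("weekday")["count"].mean().reindex(range(7)).to_numpy()


def crosstab_geo_subject(
    geo: Sequence[str], subject: Sequence[str], top_k: int = 15
) -> pd.DataFrame:
    """Percentage of each geography's articles in each subject category.

    Rows: the ``top_k`` geographies by article count (ties alphabetical)
    plus an "all" row; columns: subject labels. Each cell is
    100 * (row & column count) / (row count), so every row sums to 100
    when all subject labels (including "other") are kept.
    """
    if len(geo) != len(subject):
        raise ValueError("geo and subject length mismatch")
    if not geo:
        raise ValueError("empty input")
    df = pd.DataFrame({"geo": list(geo), "subject": list(subject)})
    geo_counts = df["geo"].value_counts()
    order = sorted(geo_counts.index, key=lambda g: (-geo_counts[g], g))[:top_k]
    subjects = sorted(df["subject"].unique())
    rows = {}
    rows["all"] = [
        100.0 * ((df["subject"] == s).sum()) / len(df) for s in subjects
    ]
    for g in order:
        sub = df[df["geo"] == g]
        rows[g] = [100.0 * ((sub["subject"] == s).sum()) / len(sub) for s in subjects]
    return pd.DataFrame.from_dict(rows, orient="index", columns=subjects)
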