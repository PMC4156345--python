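"""Aggregate time-pattern estimation.

Two questions about the rhythm of a support community are answered here:

* **When do new users arrive?**  :func:`first_time_post_series` counts, per
  calendar month, the posts made by users posting for the first time ever,
  with exact (Garwood) Poisson 95% intervals on each monthly count.

* **Which days of the week are busy?**  :func:`weekday_adjusted_means` fits
  total daily items on a saturated day-of-week factor by generalised
  estimating equations — Poisson variance, identity link, independence
  working correlation, clusters at the ISO week level — so the point
  estimates are plain per-weekday means of daily totals while the standard
  errors are robust to within-week correlation.  Weeks in which a public
  holiday or awareness day falls on a business day (Mon–Fri) are excluded
  first, because such repeating events are known to distort the weekly
  profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from .core import InteractionSet, KIND_POST

WEEKDAY_NAMES = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
                 "Saturday", "Sunday")


def load_event_calendar(path: str | Path | None = None) -> list[date]:
    """Event dates for week exclusion; the bundled NZ 2011–2012 calendar by default."""
    if path is None:
        text = resources.files("ocsn.data").joinpath("nz_events_2011_2012.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["events"]
    return [d if isinstance(d, date) else date.fromisoformat(str(d)) for d in raw]


def daily_series(
    s: InteractionSet,
    year: int | None = None,
    kinds: Sequence[str] | None = None,
) -> pd.Series:
    """Total items per day as a dense series (zero-filled) over the coverage.

    Coverage is the analysis period, restricted to *year* when given; *kinds*
    restricts to posts and/or comments.
    """
    df = s.df if kinds is None else s.df[s.df["kind"].isin(kinds)]
    start, end = pd.Timestamp(s.period_start), pd.Timestamp(s.period_end)
    if year is not None:
        start = max(start, pd.Timestamp(date(year, 1, 1)))
        end = min(end, pd.Timestamp(date(year, 12, 31)))
        df = df[(df["timestamp"] >= start) & (df["timestamp"] < end + pd.Timedelta(days=1))]
    counts = df.groupby(df["timestamp"].dt.normalize()).size()
    idx = pd.date_range(start, end, freq="D")
    return counts.reindex(idx, fill_value=0).rename("n_items")


def poisson_interval(count: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return float(lo), float(hi)


def first_time_post_series(
    s: InteractionSet, history: InteractionSet | None = None
) -> pd.DataFrame:
    """Monthly counts of first-time posts with exact Poisson 95% CIs.

    A first-time post is the first *post* (not comment) a user ever makes;
    when a history extract is supplied, users whose first post predates the
    analysis period contribute no first-time post within it.  Returns a frame
    indexed by month period with columns ``count``, ``ci_low``, ``ci_high``.
    """
    posts = s.df[s.df["kind"] == KIND_POST][["user_id", "timestamp"]]
    if history is not None:
        hist_posts = history.df[history.df["kind"] == KIND_POST][["user_id", "timestamp"]]
        posts = pd.concat([posts, hist_posts], ignore_index=True)
    if posts.empty:
        firsts = pd.Series(dtype="datetime64[ns]")
    else:
        firsts = posts.groupby("user_id")["timestamp"].min()
    start, end = pd.Timestamp(s.period_start), pd.Timestamp(s.period_end)
    in_period = firsts[(firsts >= start) & (firsts < end + pd.Timedelta(days=1))]
    monthly = in_period.dt.to_period("M").value_counts().sort_index()
    months = pd.period_range(start, end, freq="M")
    counts = monthly.reindex(months, fill_value=0)
    ci = np.array([poisson_interval(int(c)) for c in counts])
    return pd.DataFrame(
        {"count": counts.astype(int), "ci_low": ci[:, 0], "ci_high": ci[:, 1]},
        index=months,
    )


def _iso_week_key(idx: pd.DatetimeIndex) -> pd.Series:
    iso = idx.isocalendar()
    return (iso["year"].astype(int) * 100 + iso["week"].astype(int)).set_axis(idx)


def exclude_event_weeks(
    d: pd.Series, events: Iterable[date]
) -> tuple[pd.Series, list[int]]:
    """Drop every ISO week in which an event falls on a business day.

    Events landing on Saturday or Sunday exclude nothing.  Returns the
    filtered series and the sorted excluded ISO week keys (``year*100+week``).
    """
    weeks = _iso_week_key(pd.DatetimeIndex(d.index))
    bad_weeks = set()
    for ev in events:
        if ev.isoweekday() <= 5:  # Monday..Friday
            iso = ev.isocalendar()
            bad_weeks.add(iso[0] * 100 + iso[1])
    mask = ~weeks.isin(bad_weeks)
    present = set(weeks[~mask])
    return d[mask.values], sorted(present)


@dataclass
class WeekdayModelFit:
    """Cluster-adjusted weekday activity profile.

    ``table`` has one row per weekday (Monday first): adjusted mean, 95% CI,
    and the Wald z / p-value of the contrast against Monday (NaN for Monday
    itself).
    """

    table: pd.DataFrame
    n_weeks: int
    excluded_weeks: list[int]

    def mean(self, weekday: str) -> float:
        return float(self.table.set_index("weekday").loc[weekday, "mean"])


def weekday_adjusted_means(
    d: pd.Series, events: Iterable[date] = ()
) -> WeekdayModelFit:
    """GEE fit of daily totals on day of week with weekly clusters.

    Saturated weekday factor, identity link, Poisson variance, independence
    working correlation — the point estimates equal per-weekday arithmetic
    means of the daily totals; standard errors are cluster-robust (sandwich)
    over ISO weeks.  Event weeks are excluded first (see
    :func:`exclude_event_weeks`).
    """
    kept, excluded = exclude_event_weeks(d, events)
    idx = pd.DatetimeIndex(kept.index)
    weeks = _iso_week_key(idx)
    if weeks.nunique() < 2:
        raise ValueError("need at least 2 weeks of data after exclusion")
    dow = idx.dayofweek.values  # Monday=0
    for w in range(7):
        if not (dow == w).any():
            raise ValueError(f"no included data for {WEEKDAY_NAMES[w]}")

    y = kept.values.astype(float)
    exog = np.zeros((len(y), 7))
    exog[np.arange(len(y)), dow] = 1.0
    start = np.array([y[dow == w].mean() for w in range(7)])
    if (start <= 0).any():
        w = int(np.argmin(start))
        raise ValueError(f"degenerate all-zero weekday: {WEEKDAY_NAMES[w]}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y, exog,
            groups=weeks.values,
            family=sm.families.Poisson(link=sm.families.links.Identity()),
            cov_struct=sm.cov_struct.Independence(),
        )
        res = model.fit(start_params=start)

    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(0.975)
    z_vs_mon = np.full(7, np.nan)
    p_vs_mon = np.full(7, np.nan)
    for w in range(1, 7):
        diff = params[w] - params[0]
        var = max(cov[w, w] + cov[0, 0] - 2 * cov[w, 0], 0.0)
        if var == 0.0:  # degenerate: identical clusters, e.g. a constant series
            z = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        else:
            z = diff / np.sqrt(var)
        z_vs_mon[w] = z
        p_vs_mon[w] = 2 * stats.norm.sf(abs(z))

    table = pd.DataFrame({
        "weekday": WEEKDAY_NAMES,
        "mean": params,
        "ci_low": params - zcrit * se,
        "ci_high": params + zcrit * se,
        "z_vs_monday": z_vs_mon,
        "p_vs_monday": p_vs_mon,
    })
    return WeekdayModelFit(table, n_weeks=int(weeks.nunique()), excluded_weeks=excluded)
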