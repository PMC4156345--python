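"""Rolling-window engagement classification and contribution shares.

Users of a support community are grouped per calendar year by their busiest
90-day stretch:

* **HEU** (Highly Engaged User): ≥ 180 items (posts + comments) in some
  90-day window lying wholly inside the year — an average of two or more
  items per day sustained over three months;
* **MEU** (Minimally Engaged User): active during the year but never more
  than 2 items in any such window (fleeting engagement, possibly in several
  separate spells);
* **OTHER**: everyone else with at least one item that year.

The sliding window advances daily and both endpoints are constrained to the
calendar year, so a late-December item can still anchor a window reaching
back into the year but never one crossing into the next.

Group contribution shares come with percentile-bootstrap confidence
intervals obtained by resampling *users* (labels fixed, item counts
recomputed from the sampled users).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import confint_proportions_2indep, proportions_ztest

from .core import InteractionSet

HEU = "HEU"
MEU = "MEU"
OTHER = "OTHER"

DEFAULT_HEU_MIN = 180
DEFAULT_MEU_MAX = 2
DEFAULT_WINDOW_DAYS = 90


@dataclass
class UserTimeline:
    """Per-user activity record.

    ``daily_counts`` maps dates (normalised midnight Timestamps) to the number
    of items contributed that day within the analysis set;
    ``first_activity_date`` is the earliest activity over the user's *full*
    history when one is supplied, otherwise over the analysis set alone
    (``first_from_history`` records which).
    """

    user_id: str
    first_activity_date: date
    daily_counts: pd.Series  # DatetimeIndex (sorted) -> int
    first_from_history: bool = False

    @property
    def active_dates(self) -> set[date]:
        return {ts.date() for ts in self.daily_counts.index}

    @property
    def total_items(self) -> int:
        return int(self.daily_counts.sum())


def build_timelines(
    s: InteractionSet, history: InteractionSet | None = None
) -> dict[str, UserTimeline]:
    """One timeline per user with ≥ 1 item in *s*.

    *history* (a superset extract reaching before the analysis period) is used
    only to establish each user's true first date of activity.
    """
    counts = (
        s.df.groupby(["user_id", s.df["timestamp"].dt.normalize()])
        .size()
        .rename("n")
        .reset_index()
    )
    first_in_s = s.df.groupby("user_id")["timestamp"].min().dt.date
    if history is not None:
        first_hist = history.df.groupby("user_id")["timestamp"].min().dt.date
    else:
        first_hist = pd.Series(dtype=object)

    timelines: dict[str, UserTimeline] = {}
    for uid, grp in counts.groupby("user_id"):
        series = pd.Series(
            grp["n"].values, index=pd.DatetimeIndex(grp["timestamp"])
        ).sort_index()
        first = first_in_s[uid]
        from_hist = False
        if uid in first_hist.index and first_hist[uid] < first:
            first = first_hist[uid]
            from_hist = True
        timelines[uid] = UserTimeline(uid, first, series, from_hist)
    return timelines


def window_max(t: UserTimeline, year: int, window_days: int = DEFAULT_WINDOW_DAYS) -> int:
    """Maximum item count over any *window_days*-day window inside *year*.

    Windows ``[d, d + window_days - 1]`` must lie wholly within the calendar
    year; returns 0 for a year with no activity.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    year_start = pd.Timestamp(date(year, 1, 1))
    year_end = pd.Timestamp(date(year, 12, 31))
    n_days = (year_end - year_start).days + 1
    in_year = t.daily_counts[
        (t.daily_counts.index >= year_start) & (t.daily_counts.index <= year_end)
    ]
    if in_year.empty:
        return 0
    counts = np.zeros(n_days, dtype=np.int64)
    counts[(in_year.index - year_start).days] = in_year.values
    if window_days >= n_days:
        return int(counts.sum())
    sliding = np.convolve(counts, np.ones(window_days, dtype=np.int64), mode="valid")
    return int(sliding.max())


@dataclass
class EngagementClassification:
    """Per-user group assignment for one calendar year.

    ``table`` has one row per user active in the year: user_id, total_items,
    window_max, group.
    """

    year: int
    heu_min: int
    meu_max: int
    window_days: int
    table: pd.DataFrame

    def users_in(self, group: str) -> set[str]:
        return set(self.table.loc[self.table["group"] == group, "user_id"])

    def group_of(self, user_id: str) -> str | None:
        row = self.table[self.table["user_id"] == user_id]
        return None if row.empty else row["group"].iloc[0]

    def counts(self) -> dict[str, int]:
        c = self.table["group"].value_counts().to_dict()
        return {g: int(c.get(g, 0)) for g in (HEU, MEU, OTHER)}


def classify(
    timelines: dict[str, UserTimeline],
    year: int,
    heu_min: int = DEFAULT_HEU_MIN,
    meu_max: int = DEFAULT_MEU_MAX,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> EngagementClassification:
    """Assign each user active in *year* to exactly one of HEU / MEU / OTHER."""
    if heu_min <= meu_max:
        raise ValueError("heu_min must exceed meu_max")
    rows = []
    for uid in sorted(timelines):
        t = timelines[uid]
        wmax = window_max(t, year, window_days)
        mask = t.daily_counts.index.year == year
        total = int(t.daily_counts[mask].sum())
        if total == 0:
            continue
        if wmax >= heu_min:
            group = HEU
        elif wmax <= meu_max:
            group = MEU
        else:
            group = OTHER
        rows.append((uid, total, wmax, group))
    table = pd.DataFrame(rows, columns=["user_id", "total_items", "window_max", "group"])
    return EngagementClassification(year, heu_min, meu_max, window_days, table)


@dataclass
class ContributionEstimate:
    """A group's share of users and items in a year, with a bootstrap CI."""

    group: str
    year: int
    n_users: int
    share_users: float
    share_items: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    @property
    def half_width(self) -> float:
        """Half-width of the 95% interval (the ± figure in reports)."""
        return (self.ci_high - self.ci_low) / 2.0


def contribution(
    cls: EngagementClassification,
    s: InteractionSet,
    n_boot: int = 2000,
    seed: int = 0,
    groups: tuple[str, ...] = (HEU, MEU, OTHER),
) -> list[ContributionEstimate]:
    """Group item shares with percentile-bootstrap 95% CIs.

    Users are resampled with replacement; each resample keeps the fixed
    classification labels and recomputes group and total item counts from the
    sampled users' items in the year.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    year_items = s.restrict_year(cls.year)
    per_user = year_items.groupby("user_id").size()
    tab = cls.table.set_index("user_id")
    counts = per_user.reindex(tab.index, fill_value=0).to_numpy(dtype=float)
    labels = tab["group"].to_numpy()
    n_users_total = len(tab)
    total_items = counts.sum()

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_users_total, size=(n_boot, n_users_total)) if n_users_total else None

    out = []
    for g in groups:
        in_g = labels == g
        n_g = int(in_g.sum())
        if n_g == 0 or total_items == 0:
            out.append(ContributionEstimate(g, cls.year, n_g, 0.0, 0.0, 0.0, 0.0,
                                            n_boot, seed))
            continue
        share_items = counts[in_g].sum() / total_items
        share_users = n_g / n_users_total
        g_counts = np.where(in_g, counts, 0.0)
        boot_tot = counts[idx].sum(axis=1)
        boot_g = g_counts[idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            shares = np.where(boot_tot > 0, boot_g / boot_tot, 0.0)
        lo, hi = np.percentile(shares, [2.5, 97.5])
        out.append(ContributionEstimate(g, cls.year, n_g, share_users, share_items,
                                        float(lo), float(hi), n_boot, seed))
    return out


@dataclass
class GroupDynamics:
    """Year-over-year change for one engagement group."""

    group: str
    year_a: int
    year_b: int
    n_a: int
    n_b: int
    pct_growth: float | None  # None when n_a == 0
    overlap: int  # same users in the group both years
    active_in_b: int  # year-a members with any activity in year b


def group_dynamics(
    cls_a: EngagementClassification, cls_b: EngagementClassification
) -> list[GroupDynamics]:
    """Growth, overlap and retention per group across two classifications."""
    out = []
    active_b = set(cls_b.table["user_id"])
    for g in (HEU, MEU, OTHER):
        a_users = cls_a.users_in(g)
        b_users = cls_b.users_in(g)
        n_a, n_b = len(a_users), len(b_users)
        growth = None if n_a == 0 else 100.0 * (n_b - n_a) / n_a
        out.append(GroupDynamics(
            g, cls_a.year, cls_b.year, n_a, n_b, growth,
            overlap=len(a_users & b_users),
            active_in_b=len(a_users & active_b),
        ))
    return out


@dataclass
class TwoProportionResult:
    difference: float  # p2 - p1
    ci_low: float
    ci_high: float
    p_value: float


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TwoProportionResult:
    """Two-sample proportion z-test: pooled test statistic, unpooled Wald CI.

    ``difference`` is ``x2/n2 - x1/n1`` (second sample minus first).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    diff = x2 / n2 - x1 / n1
    if x1 / n1 == x2 / n2:
        p = 1.0
    else:
        _, p = proportions_ztest([x1, x2], [n1, n2])
    lo, hi = confint_proportions_2indep(x2, n2, x1, n1, method="wald", compare="diff")
    return TwoProportionResult(diff, float(lo), float(hi), float(p))
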