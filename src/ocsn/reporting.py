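"""Annual metric tables, top-user reports and distribution summaries.

The benchmarking surface of the analysis: per-year network totals and
per-user means with normal-approximation 95% margins and interquartile
ranges, year-over-year growth percentages, the top-N user table (items,
distinct active days, inclusive activity span), a Welch two-sample test for
between-year per-user means, and the cumulative activity curve showing how
concentrated contribution is across users.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InteractionSet, KIND_COMMENT, KIND_POST


def _mean_margin_iqr(values: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Mean, normal-approximation 95% margin, and midpoint-interpolated IQR."""
    mean = float(np.mean(values))
    if len(values) > 1:
        margin = 1.96 * float(np.std(values, ddof=1)) / math.sqrt(len(values))
    else:
        margin = float("nan")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="midpoint")
    return mean, margin, (float(q1), float(q3))


@dataclass
class AnnualMetrics:
    """Network user and posting metrics for one calendar year.

    Comment-per-post figures are over the year's posts, counting in-thread
    comments dated anywhere in the analysis period.
    """

    year: int
    n_posts: int
    n_comments: int
    n_first_time_posts: int
    n_unique_users: int
    mean_posts_per_user: float
    margin_posts_per_user: float
    iqr_posts_per_user: tuple[float, float]
    mean_comments_per_user: float
    margin_comments_per_user: float
    iqr_comments_per_user: tuple[float, float]
    mean_comments_per_post: float
    margin_comments_per_post: float
    iqr_comments_per_post: tuple[float, float]
    pct_posts_ge3_comments: float
    pct_posts_zero_comments: float
    empty: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def annual_metrics(
    s: InteractionSet, year: int, history: InteractionSet | None = None
) -> AnnualMetrics:
    """Totals, per-user means (with margins and IQRs) and comment distribution.

    Items are attributed to the year of their own timestamp.  First-time
    posts use the full history when supplied (a user's first post ever).
    """
    dfy = s.restrict_year(year)
    posts = dfy[dfy["kind"] == KIND_POST]
    comments = dfy[dfy["kind"] == KIND_COMMENT]
    users = dfy["user_id"].unique()
    if len(dfy) == 0:
        nan = float("nan")
        return AnnualMetrics(year, 0, 0, 0, 0, nan, nan, (nan, nan),
                             nan, nan, (nan, nan), nan, nan, (nan, nan),
                             nan, nan, empty=True)

    # first-time posts dated in the year
    all_posts = s.df[s.df["kind"] == KIND_POST][["user_id", "timestamp"]]
    if history is not None:
        all_posts = pd.concat(
            [all_posts,
             history.df[history.df["kind"] == KIND_POST][["user_id", "timestamp"]]],
            ignore_index=True)
    firsts = all_posts.groupby("user_id")["timestamp"].min()
    n_first = int((firsts.dt.year == year).sum())

    posts_per_user = posts.groupby("user_id").size().reindex(users, fill_value=0).values
    comments_per_user = (comments.groupby("user_id").size()
                         .reindex(users, fill_value=0).values)
    m_ppu, g_ppu, iqr_ppu = _mean_margin_iqr(posts_per_user)
    m_cpu, g_cpu, iqr_cpu = _mean_margin_iqr(comments_per_user)

    # comments per post: in-thread comments over the whole analysis period
    all_comments = s.df[s.df["kind"] == KIND_COMMENT]
    per_thread = all_comments.groupby("thread_id").size()
    cpp = per_thread.reindex(posts["item_id"], fill_value=0).values
    m_cpp, g_cpp, iqr_cpp = _mean_margin_iqr(cpp)

    return AnnualMetrics(
        year=year,
        n_posts=len(posts),
        n_comments=len(comments),
        n_first_time_posts=n_first,
        n_unique_users=len(users),
        mean_posts_per_user=m_ppu,
        margin_posts_per_user=g_ppu,
        iqr_posts_per_user=iqr_ppu,
        mean_comments_per_user=m_cpu,
        margin_comments_per_user=g_cpu,
        iqr_comments_per_user=iqr_cpu,
        mean_comments_per_post=m_cpp,
        margin_comments_per_post=g_cpp,
        iqr_comments_per_post=iqr_cpp,
        pct_posts_ge3_comments=100.0 * float(np.mean(cpp >= 3)),
        pct_posts_zero_comments=100.0 * float(np.mean(cpp == 0)),
    )


#: Metrics compared year over year, as (name, attribute) pairs.
GROWTH_METRICS = (
    ("all_posts", "n_posts"),
    ("all_comments", "n_comments"),
    ("first_time_posts", "n_first_time_posts"),
    ("unique_users", "n_unique_users"),
    ("mean_posts_per_user", "mean_posts_per_user"),
    ("mean_comments_per_user", "mean_comments_per_user"),
    ("mean_comments_per_post", "mean_comments_per_post"),
)


def growth(a: AnnualMetrics, b: AnnualMetrics) -> dict[str, int | None]:
    """Percentage change per metric, rounded to the nearest integer percent.

    ``None`` (flagged, not negated) where the base-year metric is zero.
    Requires ``a.year < b.year`` — swapped arguments are an error, never a
    silent sign flip.
    """
    if a.year >= b.year:
        raise ValueError("growth requires a.year < b.year")
    out: dict[str, int | None] = {}
    for name, attr in GROWTH_METRICS:
        va, vb = getattr(a, attr), getattr(b, attr)
        undefined = va == 0 or math.isnan(va) or math.isnan(vb)
        out[name] = None if undefined else round(100.0 * (vb - va) / va)
    return out


def top_users(s: InteractionSet, year: int, n: int = 20) -> pd.DataFrame:
    """Top *n* users of the year by total items, with longevity measures.

    Activity span counts both endpoint days (a user active 1 Jan–31 Dec of a
    leap year spans 366 days).  Ties in total items break by user id, so the
    ranking is stable under permutation of the input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dfy = s.restrict_year(year)
    g = dfy.groupby("user_id")
    day = dfy["timestamp"].dt.normalize()
    tab = pd.DataFrame({
        "blog_posts": g.apply(lambda x: int((x["kind"] == KIND_POST).sum()),
                              include_groups=False),
        "comments": g.apply(lambda x: int((x["kind"] == KIND_COMMENT).sum()),
                            include_groups=False),
        "distinct_days_active": day.groupby(dfy["user_id"]).nunique(),
        "first": g["timestamp"].min().dt.normalize(),
        "last": g["timestamp"].max().dt.normalize(),
    })
    tab["total_items"] = tab["blog_posts"] + tab["comments"]
    tab["activity_span_days"] = (tab["last"] - tab["first"]).dt.days + 1
    tab = (tab.sort_values(["total_items", "user_id"], ascending=[False, True],
                           kind="mergesort")
           .head(n).reset_index())
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    return tab[["rank", "user_id", "blog_posts", "comments", "total_items",
                "distinct_days_active", "activity_span_days"]]


def welch_mean_test(values_a, values_b) -> float:
    """Welch's unequal-variance two-sample t-test p-value on per-user counts."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.mean() == b.mean() and a.std() == 0 and b.std() == 0:
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def cumulative_activity_curve(s: InteractionSet, year: int | None = None) -> pd.DataFrame:
    """Cumulative item share versus user share, users sorted most active first.

    The resulting step curve is monotone nondecreasing and concave, starting
    at (0, 0) and ending at (1, 1): the height at user share *x* is the share
    of all items contributed by the most active *x* fraction of users.
    """
    df = s.df if year is None else s.restrict_year(year)
    per_user = df.groupby("user_id").size().sort_values(ascending=False)
    if per_user.empty:
        raise ValueError("no active users")
    n = len(per_user)
    share_items = np.concatenate(([0.0], np.cumsum(per_user.values) / per_user.sum()))
    share_users = np.concatenate(([0.0], np.arange(1, n + 1) / n))
    return pd.DataFrame({"share_users": share_users, "share_items": share_items})
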