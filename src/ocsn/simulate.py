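"""Seeded generator of synthetic OCSN interaction streams.

Real posting records from cessation-support communities are rarely
redistributable, so every downstream stage here is exercised on streams drawn
from a generative model that reproduces the statistical structure such an
analysis assumes:

* a **finite mixture of engagement classes** — a small highly engaged class
  that sustains months of multi-item days, a regular class active for a few
  weeks, and a large minimally engaged class that contributes an item or two
  and disappears.  The mixture, not a continuous power law, is used because it
  yields a heavy-tailed per-user activity distribution *and* categorical
  ground truth for classifier-recovery tests;
* **seasonal arrivals** — each user's first activity month follows a 12-weight
  profile (New-Year peak, late-May bump, December trough), with successive
  calendar years scaled by a growth factor;
* a **day-of-week profile** — item emission rates are modulated by 7 weekday
  weights (work-week high, Friday dip, weekend low);
* **threaded comments** — a fixed share of emitted items are posts; the rest
  are comments attached to a recent post, so the mean number of comments a
  post attracts equals ``comment_rate``;
* **artifacts** — accidental verbatim re-submissions seconds after the
  original, and replies from a single reserved staff account; both are
  injected on top of a clean stream and fully flagged in the ground truth so
  the cleaning pipeline can be checked exactly.

Identical configs (same seed) produce bit-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import InteractionSet, make_interaction_set

#: Reserved author id for injected staff replies.
STAFF_USER_ID = "staff"

_SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class EngagementClass:
    """One component of the engagement mixture.

    ``mean_items_per_active_day`` is the Poisson rate on an average weekday
    (the realised rate is modulated by the weekday weights); at least one item
    is always emitted on the first active day, which is what makes the drawn
    first-activity date observable.  ``mean_active_days`` is the expected
    number of distinct active days; active days after the first are drawn with
    exponentially decaying probability (scale ``decay_days``) so activity
    concentrates in a user's early life, as it does for new members of a
    support community.
    """

    label: str
    proportion: float
    mean_items_per_active_day: float
    mean_active_days: float
    decay_days: float = 60.0


DEFAULT_MIXTURE = (
    EngagementClass("high", 0.03, 8.0, 180.0, 240.0),
    EngagementClass("regular", 0.57, 1.5, 25.0, 45.0),
    EngagementClass("minimal", 0.40, 0.55, 1.2, 30.0),
)

#: First-activity month weights, January..December.
DEFAULT_MONTHLY_WEIGHTS = (1.6, 1.2, 1.05, 0.95, 1.3, 1.0, 0.95, 0.9, 0.85, 0.8, 0.7, 0.5)
#: Item-rate weights, Monday..Sunday.
DEFAULT_WEEKDAY_WEIGHTS = (1.25, 1.2, 1.2, 1.1, 0.85, 0.6, 0.55)


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic network generator."""

    n_users: int = 2000
    period_start: date = date(2011, 1, 1)
    period_end: date = date(2012, 12, 31)
    engagement_mixture: tuple[EngagementClass, ...] = DEFAULT_MIXTURE
    monthly_arrival_weights: tuple[float, ...] = DEFAULT_MONTHLY_WEIGHTS
    weekday_weights: tuple[float, ...] = DEFAULT_WEEKDAY_WEIGHTS
    annual_arrival_growth: float = 1.5
    comment_rate: float = 6.0
    staff_reply_prob: float = 0.06
    duplicate_prob: float = 0.004
    mean_post_words: float = 14.0
    mean_comment_words: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = [c.proportion for c in self.engagement_mixture]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if any(p < 0 for p in props):
            raise ValueError("mixing proportions must be nonnegative")
        for c in self.engagement_mixture:
            if c.mean_items_per_active_day < 0 or c.mean_active_days < 1 or c.decay_days <= 0:
                raise ValueError(f"negative or degenerate rates in class {c.label!r}")
        if len(self.monthly_arrival_weights) != 12 or len(self.weekday_weights) != 7:
            raise ValueError("need 12 monthly and 7 weekday weights")
        if min(self.monthly_arrival_weights) < 0 or min(self.weekday_weights) < 0:
            raise ValueError("weights must be nonnegative")
        for p in (self.staff_reply_prob, self.duplicate_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.comment_rate < 0:
            raise ValueError("comment_rate must be nonnegative")
        if self.n_users < 0:
            raise ValueError("n_users must be nonnegative")
        if self.period_end < self.period_start:
            raise ValueError("period_end before period_start")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["period_start"] = self.period_start.isoformat()
        d["period_end"] = self.period_end.isoformat()
        d["engagement_mixture"] = [asdict(c) for c in self.engagement_mixture]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("period_start", "period_end"):
            if isinstance(d.get(key), str):
                d[key] = date.fromisoformat(d[key])
        if "engagement_mixture" in d:
            d["engagement_mixture"] = tuple(
                EngagementClass(**c) if isinstance(c, dict) else c
                for c in d["engagement_mixture"]
            )
        for key in ("monthly_arrival_weights", "weekday_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Per-user classes and per-item artifact flags for a simulated stream.

    ``users``: user_id, true_class, first_activity_date.
    ``items``: item_id, is_injected_duplicate, is_staff.
    """

    users: pd.DataFrame
    items: pd.DataFrame

    @property
    def clean_item_ids(self) -> set[str]:
        """Ids of items that are neither injected duplicates nor staff items."""
        clean = ~(self.items["is_injected_duplicate"] | self.items["is_staff"])
        return set(self.items.loc[clean, "item_id"])

    def to_jsonl(self, users_path: str | Path, items_path: str | Path) -> None:
        u = self.users.copy()
        u["first_activity_date"] = u["first_activity_date"].astype(str)
        u.to_json(users_path, orient="records", lines=True)
        self.items.to_json(items_path, orient="records", lines=True)


# ---------------------------------------------------------------------------
# text generation


def _vocabulary() -> list[str]:
    """A deterministic pseudo-word vocabulary (~600 pronounceable tokens)."""
    syllables = [c + v for c in "bdfglmnprstvz" for v in "aeiou"]
    words = ["".join(p) for p in itertools.product(syllables, repeat=2)]
    return words[:600]


_VOCAB = np.array(_vocabulary())


def _draw_texts(rng: np.random.Generator, n: int, mean_words: float) -> list[str]:
    counts = 3 + rng.poisson(max(mean_words - 3.0, 0.0), size=n)
    flat = rng.integers(0, len(_VOCAB), size=int(counts.sum()))
    words = _VOCAB[flat]
    out, pos = [], 0
    for c in counts:
        out.append(" ".join(words[pos:pos + c]))
        pos += c
    return out


def _ensure_unique_within_thread(
    df: pd.DataFrame, rng: np.random.Generator, mean_words: float
) -> None:
    """Re-roll texts so no two items in a thread share a text (in place).

    Accidental duplicates are modelled exclusively by :func:`inject_artifacts`;
    the base stream must therefore be duplicate-free by construction.
    """
    for _ in range(20):
        clash = df.duplicated(subset=["thread_id", "text"], keep="first")
        if not clash.any():
            return
        df.loc[clash, "text"] = _draw_texts(rng, int(clash.sum()), mean_words)
    raise RuntimeError("could not make thread texts unique")


# ---------------------------------------------------------------------------
# main generator


def _empty_truth() -> GroundTruth:
    return GroundTruth(
        users=pd.DataFrame(columns=["user_id", "true_class", "first_activity_date"]),
        items=pd.DataFrame(columns=["item_id", "is_injected_duplicate", "is_staff"]),
    )


def _draw_first_dates(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """First-activity dates as day offsets from period_start."""
    start, end = config.period_start, config.period_end
    years = list(range(start.year, end.year + 1))
    year_w = np.array([config.annual_arrival_growth ** i for i in range(len(years))])
    month_w = np.asarray(config.monthly_arrival_weights, dtype=float)

    # enumerate candidate (year, month) cells with their day ranges inside the period
    cells = []
    weights = []
    for yi, y in enumerate(years):
        for m in range(1, 13):
            first = date(y, m, 1)
            last = (date(y + 1, 1, 1) if m == 12 else date(y, m + 1, 1)) - timedelta(days=1)
            lo, hi = max(first, start), min(last, end)
            if lo > hi:
                continue
            cells.append((lo, (hi - lo).days + 1))
            weights.append(year_w[yi] * month_w[m - 1])
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        raise ValueError("arrival weights are all zero on the period")
    cell_idx = rng.choice(len(cells), size=n, p=weights / weights.sum())
    days_in_cell = np.array([cells[i][1] for i in cell_idx])
    day = rng.integers(0, days_in_cell)
    cell_start = np.array([(cells[i][0] - start).days for i in cell_idx])
    return cell_start + day


def simulate_network(config: SimConfig) -> tuple[InteractionSet, GroundTruth]:
    """Draw a full synthetic interaction stream (no artifacts).

    Each user draws an engagement class, a first-activity date and an
    active-day set; on each active day the user emits a Poisson number of
    items (at least one on the first day) at a rate modulated by the weekday
    weights.  A share ``1 / (1 + comment_rate)`` of items become posts; the
    remainder become comments on a post from the preceding seven days, so
    posts attract ``comment_rate`` comments on average.
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.period_start, config.period_end
    if config.n_users == 0:
        return (
            make_interaction_set(pd.DataFrame(columns=["item_id", "user_id", "timestamp",
                                                       "kind", "thread_id", "text"]),
                                 start, end),
            _empty_truth(),
        )

    n = config.n_users
    horizon_days = (end - start).days
    classes = config.engagement_mixture
    cls_idx = rng.choice(len(classes), size=n,
                         p=[c.proportion for c in classes])
    first_off = _draw_first_dates(config, rng, n)

    wk = np.asarray(config.weekday_weights, dtype=float)
    wk_factor = wk * 7.0 / wk.sum()
    start_dow = start.weekday()  # Monday=0

    user_idx_parts, day_parts, count_parts = [], [], []
    for u in range(n):
        c = classes[cls_idx[u]]
        f = int(first_off[u])
        avail = horizon_days - f  # offsets 0..avail usable
        if c.mean_active_days >= avail + 1:
            offs = np.arange(avail + 1)
        else:
            n_act = 1 + rng.poisson(max(c.mean_active_days - 1.0, 0.0))
            n_act = min(n_act, avail + 1)
            if n_act > 1:
                cand = np.arange(1, avail + 1)
                w = np.exp(-cand / c.decay_days)
                w_sum = w.sum()
                if w_sum <= 0:
                    extra = rng.choice(cand, size=n_act - 1, replace=False)
                else:
                    extra = rng.choice(cand, size=n_act - 1, replace=False, p=w / w_sum)
                offs = np.concatenate(([0], np.sort(extra)))
            else:
                offs = np.array([0])
        days = f + offs
        lam = c.mean_items_per_active_day * wk_factor[(start_dow + days) % 7]
        counts = rng.poisson(lam)
        counts[0] = max(1, counts[0])
        keep = counts > 0
        day_parts.append(days[keep])
        count_parts.append(counts[keep])
        user_idx_parts.append(np.full(keep.sum(), u))

    day_of = np.concatenate(day_parts)
    counts = np.concatenate(count_parts)
    users_of = np.concatenate(user_idx_parts)

    item_user = np.repeat(users_of, counts)
    item_day = np.repeat(day_of, counts)
    n_items = len(item_user)
    item_sec = item_day * _SECONDS_PER_DAY + rng.integers(0, _SECONDS_PER_DAY, size=n_items)

    order = np.argsort(item_sec, kind="stable")
    item_user = item_user[order]
    item_sec = item_sec[order]

    p_post = 1.0 / (1.0 + config.comment_rate)
    want_post = rng.random(n_items) < p_post
    pick_u = rng.random(n_items)

    user_ids = np.array([f"u{u:05d}" for u in range(n)])
    item_ids = np.array([f"i{j:08d}" for j in range(n_items)])
    kinds = np.empty(n_items, dtype=object)
    threads = np.empty(n_items, dtype=object)

    recent: list[tuple[int, str]] = []  # (seconds, post item_id), time-ordered
    head = 0
    window = 7 * _SECONDS_PER_DAY
    for j in range(n_items):
        t = item_sec[j]
        while head < len(recent) and t - recent[head][0] > window:
            head += 1
        live = len(recent) - head
        if want_post[j] or live == 0:
            kinds[j] = "post"
            threads[j] = item_ids[j]
            recent.append((t, item_ids[j]))
        else:
            kinds[j] = "comment"
            threads[j] = recent[head + int(pick_u[j] * live)][1]

    is_post = kinds == "post"
    texts = np.empty(n_items, dtype=object)
    texts[is_post] = _draw_texts(rng, int(is_post.sum()), config.mean_post_words)
    texts[~is_post] = _draw_texts(rng, int((~is_post).sum()), config.mean_comment_words)

    df = pd.DataFrame({
        "item_id": item_ids,
        "user_id": user_ids[item_user],
        "timestamp": pd.Timestamp(start) + pd.to_timedelta(item_sec, unit="s"),
        "kind": kinds,
        "thread_id": threads,
        "text": texts,
    })
    _ensure_unique_within_thread(df, rng, config.mean_comment_words)

    stream = make_interaction_set(df, start, end)
    truth = GroundTruth(
        users=pd.DataFrame({
            "user_id": user_ids,
            "true_class": [classes[i].label for i in cls_idx],
            "first_activity_date": [start + timedelta(days=int(d)) for d in first_off],
        }),
        items=pd.DataFrame({
            "item_id": item_ids,
            "is_injected_duplicate": False,
            "is_staff": False,
        }),
    )
    return stream, truth


def truncate_items(s: InteractionSet, n: int) -> InteractionSet:
    """Keep the earliest *n* items (by timestamp, then item id).

    Truncation can orphan comments whose root post is cut; downstream loaders
    and the cleaner tolerate orphans, so this is a safe way to fix the exact
    size of a raw extract.
    """
    ordered = s.df.sort_values(["timestamp", "item_id"], kind="mergesort").head(n)
    return InteractionSet(ordered.reset_index(drop=True), s.period_start, s.period_end)


def inject_artifacts(
    s: InteractionSet,
    config: SimConfig,
    truth: GroundTruth | None = None,
    n_duplicates: int | None = None,
    n_staff_comments: int | None = None,
) -> tuple[InteractionSet, GroundTruth]:
    """Add verbatim re-submissions and staff replies to a clean stream.

    By default each item is re-submitted verbatim 1–60 s later with
    probability ``config.duplicate_prob`` and each post attracts one staff
    comment with probability ``config.staff_reply_prob``.  Passing
    ``n_duplicates`` / ``n_staff_comments`` instead injects exactly those
    counts (duplicates of distinct items; staff replies on distinct posts).
    All injected items are flagged in the returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng([config.seed, 7919])
    df = s.df
    if truth is None:
        truth = GroundTruth(
            users=pd.DataFrame(columns=["user_id", "true_class", "first_activity_date"]),
            items=pd.DataFrame({
                "item_id": df["item_id"],
                "is_injected_duplicate": False,
                "is_staff": False,
            }),
        )
    if (truth.items["is_injected_duplicate"] | truth.items["is_staff"]).any():
        raise ValueError("stream already carries injected artifacts")

    end_ts = pd.Timestamp(s.period_end) + pd.Timedelta(hours=23, minutes=59, seconds=59)

    # -- duplicates --------------------------------------------------------
    if n_duplicates is None:
        dup_mask = rng.random(len(df)) < config.duplicate_prob
        dup_rows = df[dup_mask]
    else:
        if n_duplicates > len(df):
            raise ValueError("cannot duplicate more items than exist")
        pick = rng.choice(len(df), size=n_duplicates, replace=False)
        dup_rows = df.iloc[np.sort(pick)]
    dup = dup_rows.copy()
    dup["item_id"] = [f"zdup{j:06d}" for j in range(len(dup))]
    dup["timestamp"] = dup["timestamp"] + pd.to_timedelta(
        rng.integers(1, 61, size=len(dup)), unit="s"
    )
    dup["timestamp"] = dup["timestamp"].clip(upper=end_ts)
    # re-submissions land in the same thread as plain comments (a re-submitted
    # post does not open a new thread), mirroring accidental double-submits
    dup["thread_id"] = dup_rows["thread_id"].values
    dup["kind"] = "comment"

    # -- staff replies -----------------------------------------------------
    posts = df[df["kind"] == "post"]
    if n_staff_comments is None:
        staff_mask = rng.random(len(posts)) < config.staff_reply_prob
        staff_targets = posts[staff_mask]
    else:
        if n_staff_comments > len(posts):
            raise ValueError("cannot add more staff replies than posts")
        pick = rng.choice(len(posts), size=n_staff_comments, replace=False)
        staff_targets = posts.iloc[np.sort(pick)]
    staff = pd.DataFrame({
        "item_id": [f"zstaff{j:06d}" for j in range(len(staff_targets))],
        "user_id": STAFF_USER_ID,
        "timestamp": (staff_targets["timestamp"]
                      + pd.to_timedelta(rng.integers(600, _SECONDS_PER_DAY,
                                                     size=len(staff_targets)), unit="s")
                      ).clip(upper=end_ts).values,
        "kind": "comment",
        "thread_id": staff_targets["thread_id"].values,
        "text": _draw_texts(rng, len(staff_targets), config.mean_comment_words),
    })
    # staff texts must not collide with anything already in the thread
    if len(staff):
        existing = pd.concat([df[["thread_id", "text"]], dup[["thread_id", "text"]]])
        for _ in range(20):
            merged = staff.merge(existing, on=["thread_id", "text"], how="left",
                                 indicator=True)
            clash = (merged["_merge"] == "both").values | staff.duplicated(
                subset=["thread_id", "text"], keep="first").values
            if not clash.any():
                break
            staff.loc[clash, "text"] = _draw_texts(rng, int(clash.sum()),
                                                   config.mean_comment_words)

    out = pd.concat(
        [df, dup[df.columns], staff[[c for c in df.columns if c in staff.columns]]],
        ignore_index=True,
    )
    out = out.sort_values(["timestamp", "item_id"], kind="mergesort").reset_index(drop=True)
    new_items = pd.concat([
        truth.items,
        pd.DataFrame({"item_id": dup["item_id"],
                      "is_injected_duplicate": True, "is_staff": False}),
        pd.DataFrame({"item_id": staff["item_id"],
                      "is_injected_duplicate": False, "is_staff": True}),
    ], ignore_index=True)
    stream = make_interaction_set(out, s.period_start, s.period_end)
    return stream, GroundTruth(users=truth.users, items=new_items)
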