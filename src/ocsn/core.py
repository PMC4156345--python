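"""Domain types, file I/O and the cleaning pipeline for interaction streams.

An *interaction* is a single blog post or a comment on a post in an online
cessation support network (OCSN).  The raw extract of such a network is a flat
table with one row per item: an opaque item id, the authoring account, a
timestamp, the kind (post/comment), the id of the thread's root post, and the
item text (or a content surrogate: whitespace word count plus a SHA-1 digest of
the exact text bytes).

Cleaning turns a raw extract into the analysis set in two steps:

1. **Deduplication** — within each thread, items sharing a text digest are
   collapsed to the single earliest item (accidental rapid double-submissions
   and replicated accounts produce verbatim copies).
2. **Account exclusion** — items authored by designated service-staff accounts
   are dropped (a single staff account answers practical questions and is not
   part of peer-to-peer interaction).

Both steps report exactly what they removed so that
``n_raw = n_final + n_duplicates_removed + n_staff_removed`` always holds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

KIND_POST = "post"
KIND_COMMENT = "comment"
KINDS = (KIND_POST, KIND_COMMENT)

#: Columns every extract must provide.
REQUIRED_COLUMNS = ("item_id", "user_id", "timestamp", "kind", "thread_id")
#: Full canonical column order of an interaction table.
COLUMNS = list(REQUIRED_COLUMNS) + ["text", "word_count", "text_hash"]


def text_digest(text: str) -> str:
    """SHA-1 hex digest of the exact UTF-8 text bytes (no normalisation)."""
    return hashlib.sha1(text.encode("utf-8")).hexdigest()


def word_count(text: str) -> int:
    """Number of whitespace-delimited tokens of *text*."""
    return len(text.split())


@dataclass(frozen=True)
class Interaction:
    """A single post or comment (record form of one table row)."""

    item_id: str
    user_id: str
    timestamp: pd.Timestamp
    kind: str
    thread_id: str
    text: str | None = None
    word_count: int | None = None
    text_hash: str | None = None


@dataclass
class InteractionSet:
    """An interaction table together with its closed analysis period.

    ``df`` holds one row per item with the canonical columns; ``orphan_ids``
    lists comments whose ``thread_id`` matched no post at load time (kept, not
    discarded).
    """

    df: pd.DataFrame
    period_start: date
    period_end: date
    orphan_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def item_ids(self) -> pd.Series:
        return self.df["item_id"]

    def posts(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == KIND_POST]

    def comments(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == KIND_COMMENT]

    def iter_interactions(self) -> Iterable[Interaction]:
        for row in self.df.itertuples(index=False):
            yield Interaction(
                row.item_id, row.user_id, row.timestamp, row.kind,
                row.thread_id, row.text,
                None if pd.isna(row.word_count) else int(row.word_count),
                row.text_hash,
            )

    def restrict_year(self, year: int) -> pd.DataFrame:
        """Rows whose timestamp falls in calendar *year*."""
        return self.df[self.df["timestamp"].dt.year == year]


@dataclass
class CleaningReport:
    """Accounting of what the cleaning pipeline removed."""

    n_raw: int
    n_duplicates_removed: int
    n_staff_removed: int
    n_final: int
    duplicate_item_ids: list[str] = field(default_factory=list)
    staff_item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_final != self.n_raw - self.n_duplicates_removed - self.n_staff_removed:
            raise ValueError("cleaning counts do not balance")
        if set(self.duplicate_item_ids) & set(self.staff_item_ids):
            raise ValueError("duplicate and staff id lists must be disjoint")

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_staff_removed": self.n_staff_removed,
            "n_final": self.n_final,
            "duplicate_item_ids": list(self.duplicate_item_ids),
            "staff_item_ids": list(self.staff_item_ids),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and fill content-surrogate columns from text."""
    df = df.copy()
    for col in ("text", "word_count", "text_hash"):
        if col not in df.columns:
            df[col] = None
    df["text"] = df["text"].astype(object).where(df["text"].notna(), None)
    has_text = df["text"].notna()
    df.loc[has_text, "word_count"] = df.loc[has_text, "text"].map(word_count)
    df.loc[has_text, "text_hash"] = df.loc[has_text, "text"].map(text_digest)
    df["word_count"] = df["word_count"].astype("Int64")
    for col in ("item_id", "user_id", "kind", "thread_id"):
        df[col] = df[col].astype(str)
    return df[COLUMNS]


def make_interaction_set(
    df: pd.DataFrame,
    period_start: date | None = None,
    period_end: date | None = None,
) -> InteractionSet:
    """Validate a raw interaction frame and wrap it as an :class:`InteractionSet`.

    Computes ``word_count``/``text_hash`` wherever text is present, checks item
    id uniqueness, the post/thread self-reference invariant and the period
    bounds, and flags (without discarding) comments whose thread root is
    missing from the set.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required field: {col!r}")
    df = _normalise_frame(df)
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        raise ValueError(f"unparseable timestamp at row index {bad.idxmax()}")
    if ts.isna().any():
        raise ValueError(f"missing timestamp at row index {ts.isna().idxmax()}")
    df["timestamp"] = ts

    bad_kind = ~df["kind"].isin(KINDS)
    if bad_kind.any():
        raise ValueError(f"unknown kind {df.loc[bad_kind.idxmax(), 'kind']!r}")
    if df["item_id"].duplicated().any():
        dup = df.loc[df["item_id"].duplicated(), "item_id"].iloc[0]
        raise ValueError(f"duplicate item_id {dup!r}")

    is_post = df["kind"] == KIND_POST
    if (df.loc[is_post, "thread_id"] != df.loc[is_post, "item_id"]).any():
        raise ValueError("post with thread_id != item_id")

    dates = df["timestamp"].dt.date
    if period_start is None:
        period_start = dates.min() if len(df) else date(1970, 1, 1)
    if period_end is None:
        period_end = dates.max() if len(df) else date(1970, 1, 1)
    if len(df) and ((dates < period_start).any() or (dates > period_end).any()):
        raise ValueError("timestamp outside the analysis period")

    post_ids = set(df.loc[is_post, "item_id"])
    orphans = df.loc[~is_post & ~df["thread_id"].isin(post_ids), "item_id"]
    if len(orphans):
        logger.warning("loaded %d orphan comments (thread root missing)", len(orphans))
    return InteractionSet(
        df.reset_index(drop=True), period_start, period_end,
        orphan_ids=tuple(orphans),
    )


def read_interactions(
    path: str | Path,
    format: str | None = None,
    period_start: date | None = None,
    period_end: date | None = None,
) -> InteractionSet:
    """Read an interaction extract from CSV or JSON-lines.

    The format is inferred from the suffix (``.csv`` / ``.jsonl``) unless given
    explicitly.  Missing required columns and unparseable timestamps are hard
    errors; orphan comments are loaded and logged.
    """
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str)
    elif fmt == "jsonl":
        df = pd.read_json(path, lines=True, dtype=str)
        if df.empty:
            df = pd.DataFrame(columns=COLUMNS)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return make_interaction_set(df, period_start, period_end)


def write_interactions(s: InteractionSet, path: str | Path, format: str | None = None) -> None:
    """Write an interaction set to CSV or JSON-lines with ISO-8601 timestamps."""
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv")
    out = s.df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    if fmt == "csv":
        out.to_csv(path, index=False)
    elif fmt == "jsonl":
        out.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def deduplicate(s: InteractionSet) -> tuple[InteractionSet, CleaningReport]:
    """Collapse within-thread exact-text duplicates to the earliest item.

    Items are compared by their text digest *within a thread only*; the same
    text appearing in two different threads is retained.  Among duplicates the
    earliest timestamp survives, ties broken by smallest item id.  Every item
    must carry text or a precomputed digest.
    """
    df = s.df
    missing = df["text"].isna() & df["text_hash"].isna()
    if missing.any():
        raise ValueError(
            f"item {df.loc[missing.idxmax(), 'item_id']!r} lacks both text and text_hash"
        )
    ordered = df.sort_values(["timestamp", "item_id"], kind="mergesort")
    removed_mask = ordered.duplicated(subset=["thread_id", "text_hash"], keep="first")
    removed_ids = ordered.loc[removed_mask, "item_id"].tolist()
    keep = df[~df["item_id"].isin(removed_ids)].reset_index(drop=True)
    report = CleaningReport(
        n_raw=len(df),
        n_duplicates_removed=len(removed_ids),
        n_staff_removed=0,
        n_final=len(keep),
        duplicate_item_ids=sorted(removed_ids),
    )
    return InteractionSet(keep, s.period_start, s.period_end, s.orphan_ids), report


def exclude_accounts(
    s: InteractionSet, account_ids: Sequence[str]
) -> tuple[InteractionSet, CleaningReport]:
    """Remove every item authored by any of the listed accounts."""
    mask = s.df["user_id"].isin(set(map(str, account_ids)))
    removed_ids = s.df.loc[mask, "item_id"].tolist()
    keep = s.df[~mask].reset_index(drop=True)
    report = CleaningReport(
        n_raw=len(s.df),
        n_duplicates_removed=0,
        n_staff_removed=len(removed_ids),
        n_final=len(keep),
        staff_item_ids=sorted(removed_ids),
    )
    return InteractionSet(keep, s.period_start, s.period_end, s.orphan_ids), report


def clean_pipeline(
    s: InteractionSet, staff_ids: Sequence[str]
) -> tuple[InteractionSet, CleaningReport]:
    """Deduplicate, then drop staff items; report aggregates both stages."""
    dedup, r1 = deduplicate(s)
    final, r2 = exclude_accounts(dedup, staff_ids)
    report = CleaningReport(
        n_raw=r1.n_raw,
        n_duplicates_removed=r1.n_duplicates_removed,
        n_staff_removed=r2.n_staff_removed,
        n_final=r2.n_final,
        duplicate_item_ids=r1.duplicate_item_ids,
        staff_item_ids=r2.staff_item_ids,
    )
    return final, report
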