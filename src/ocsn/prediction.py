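"""Early identification of Minimally Engaged Users (MEUs).

Interventions aimed at re-engaging users who drift away almost immediately
need to spot them *early*.  This module asks whether a user's very first day
or first week of activity predicts MEU status over the following 90 days
(≤ 2 items in the follow-up window), using plain maximum-likelihood logistic
regression evaluated on a random 30% holdout:

* the **first-day** model uses number of posts, number of comments made,
  share of the user's items that are comments, and total words written;
* the **first-week** model needs only the number of posts and the number of
  comments made.

A score above 0.5 predicts MEU (a score of exactly 0.5 predicts non-MEU).
Discrimination is summarised by sensitivity, specificity and the AUROC —
implemented directly as the Mann–Whitney rank statistic: the probability a
random MEU scores above a random non-MEU, ties counted half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from datetime import date
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .core import InteractionSet, KIND_COMMENT, KIND_POST

FIRST_DAY = "first_day"
FIRST_WEEK = "first_week"

#: Candidate early-activity variables (distinct active days is first-week only).
CANDIDATE_VARIABLES = (
    "n_posts",
    "n_comments_made",
    "pct_comments",
    "n_distinct_active_days",
    "n_comments_received",
    "mean_distinct_commenters_per_post",
    "total_words",
)

#: Variable sets retained by default for each observation window.
DEFAULT_VARIABLES = {
    FIRST_DAY: ("n_posts", "n_comments_made", "pct_comments", "total_words"),
    FIRST_WEEK: ("n_posts", "n_comments_made"),
}

FOLLOWUP_DAYS = 90
MEU_MAX_ITEMS = 2


def first_time_cohort(
    s: InteractionSet,
    start: date,
    end: date,
    history: InteractionSet | None = None,
) -> pd.DataFrame:
    """Users whose first-ever activity date falls in [start, end].

    Returns a frame with ``user_id`` and ``start_date`` (the first activity
    date).  A history extract, when given, removes users who were already
    active before the analysis period.
    """
    firsts = s.df.groupby("user_id")["timestamp"].min().dt.date
    if history is not None:
        hist = history.df.groupby("user_id")["timestamp"].min().dt.date
        firsts = pd.concat([firsts, hist]).groupby(level=0).min()
    keep = firsts[(firsts >= start) & (firsts <= end)]
    return (
        keep.rename("start_date").reset_index().sort_values("user_id")
        .reset_index(drop=True)
    )


def _window_days(window: str) -> int:
    if window == FIRST_DAY:
        return 1
    if window == FIRST_WEEK:
        return 7
    raise ValueError(f"unknown window {window!r}")


def extract_features(
    s: InteractionSet, cohort: pd.DataFrame, window: str
) -> pd.DataFrame:
    """One early-activity feature vector per cohort user.

    The window is the user's first calendar date of activity (``first_day``)
    or that date plus the following six days (``first_week``).  Comments
    received count only comments by *other* users, made within the window, on
    posts the user made within the window.
    """
    w = _window_days(window)
    df = s.df
    starts = cohort.set_index("user_id")["start_date"]

    merged = df.merge(starts.rename("start_date"), left_on="user_id", right_index=True)
    day = merged["timestamp"].dt.date
    off = (pd.to_datetime(day) - pd.to_datetime(merged["start_date"])).dt.days
    own = merged[(off >= 0) & (off < w)]

    n_posts = own[own["kind"] == KIND_POST].groupby("user_id").size()
    n_comments = own[own["kind"] == KIND_COMMENT].groupby("user_id").size()
    words = own.groupby("user_id")["word_count"].sum()
    active_days = own.groupby("user_id")["timestamp"].apply(lambda t: t.dt.date.nunique())

    # comments received: by others, within the *author's* window, on window posts
    win_posts = own[own["kind"] == KIND_POST][["item_id", "user_id", "start_date"]]
    all_comments = df[df["kind"] == KIND_COMMENT][["user_id", "thread_id", "timestamp"]]
    recv = all_comments.merge(
        win_posts, left_on="thread_id", right_on="item_id",
        suffixes=("_commenter", "_author"),
    )
    recv = recv[recv["user_id_commenter"] != recv["user_id_author"]]
    c_off = (recv["timestamp"].dt.normalize()
             - pd.to_datetime(recv["start_date"])).dt.days
    recv = recv[(c_off >= 0) & (c_off < w)]
    n_received = recv.groupby("user_id_author").size()
    commenters_per_post = recv.groupby(["user_id_author", "thread_id"])[
        "user_id_commenter"].nunique()
    mean_commenters = (
        commenters_per_post.groupby("user_id_author").sum()
        / win_posts.groupby("user_id").size()
    )

    out = pd.DataFrame({"user_id": cohort["user_id"].values}).set_index("user_id")
    out["window"] = window
    out["n_posts"] = n_posts.reindex(out.index, fill_value=0).astype(int)
    out["n_comments_made"] = n_comments.reindex(out.index, fill_value=0).astype(int)
    denom = out["n_posts"] + out["n_comments_made"]
    out["pct_comments"] = np.where(denom > 0, out["n_comments_made"] / denom, 0.0)
    out["n_distinct_active_days"] = (
        active_days.reindex(out.index, fill_value=0).astype(int) if w > 1 else 1
    )
    out["n_comments_received"] = n_received.reindex(out.index, fill_value=0).astype(int)
    out["mean_distinct_commenters_per_post"] = (
        mean_commenters.reindex(out.index).fillna(0.0)
    )
    out["total_words"] = words.reindex(out.index, fill_value=0).astype(int)
    return out.reset_index()


def label_meu(
    s_with_followup: InteractionSet, cohort: pd.DataFrame
) -> pd.DataFrame:
    """MEU label per cohort user: ≤ 2 items in the 90 days from the start date.

    Requires the data to extend at least 90 days past every start date.
    """
    last_needed = pd.to_datetime(cohort["start_date"]) + pd.Timedelta(days=FOLLOWUP_DAYS - 1)
    short = last_needed.dt.date > s_with_followup.period_end
    if short.any():
        missing = cohort.loc[short, "user_id"].tolist()
        raise ValueError(f"insufficient follow-up for users: {missing}")
    df = s_with_followup.df
    merged = df.merge(cohort.set_index("user_id")["start_date"],
                      left_on="user_id", right_index=True)
    off = (merged["timestamp"].dt.normalize()
           - pd.to_datetime(merged["start_date"])).dt.days
    in_follow = merged[(off >= 0) & (off < FOLLOWUP_DAYS)]
    counts = in_follow.groupby("user_id").size()
    out = cohort.copy()
    out["n_followup_items"] = counts.reindex(cohort["user_id"]).fillna(0).astype(int).values
    out["label"] = out["n_followup_items"] <= MEU_MAX_ITEMS
    return out


def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann–Whitney rank statistic.

    The probability a randomly chosen positive outranks a randomly chosen
    negative, with tied scores counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class DiscriminationReport:
    """Holdout discrimination of an MEU model at the 0.5 score cut."""

    window: str
    variables: tuple[str, ...]
    seed: int
    n_train: int
    n_test: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auroc: float
    cut: float = 0.5
    separation_flagged: bool = False

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class MEUModel:
    """A fitted early-MEU logistic model."""

    window: str
    variables: tuple[str, ...]
    params: pd.Series  # const + variables
    separation_flagged: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(features[list(self.variables)].astype(float), has_constant="add")
        lin = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unregularised MLE logistic fit; returns (params, separation_flagged)."""
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            params = np.asarray(res.params)
        except Exception:
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=0)
            params = np.asarray(res.params)
            flagged = True
        if any("separation" in str(w.message).lower() for w in caught):
            flagged = True
    if np.abs(params).max() > 1e3:
        flagged = True
    return params, flagged


def fit_meu_model(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    train_frac: float = 0.70,
    seed: int = 0,
    variables: tuple[str, ...] | None = None,
    cut: float = 0.5,
) -> tuple[MEUModel, DiscriminationReport]:
    """Fit and evaluate an early-MEU logistic model on a random holdout.

    A simple random ``train_frac`` share of users estimates the coefficients
    (maximum likelihood, no regularisation); the remaining users form the
    holdout on which sensitivity, specificity (at the score cut) and AUROC
    are reported.  Complete separation flags the fit but still yields a
    report from the fitted scores.
    """
    window = features["window"].iloc[0]
    variables = tuple(variables or DEFAULT_VARIABLES[window])
    data = features.merge(labels[["user_id", "label"]], on="user_id")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(data))
    n_train = int(round(train_frac * len(data)))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    train, test = data.iloc[train_idx], data.iloc[test_idx]
    if train["label"].nunique() < 2:
        raise ValueError("both classes must be present in training data")

    Xtr = sm.add_constant(train[list(variables)].astype(float), has_constant="add")
    params, flagged = _fit_logistic(Xtr.to_numpy(), train["label"].to_numpy(float))
    model = MEUModel(window, variables,
                     pd.Series(params, index=["const", *variables]), flagged)

    scores = model.predict(test)
    y = test["label"].to_numpy(bool)
    pred = scores > cut
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    report = DiscriminationReport(
        window=window, variables=variables, seed=seed,
        n_train=len(train), n_test=len(test),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auroc=auroc(scores, y),
        cut=cut,
        separation_flagged=flagged,
    )
    return model, report


def search_variable_subsets(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    train_frac: float = 0.70,
    seed: int = 0,
    candidates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Exhaustive holdout-AUROC search over candidate variable subsets.

    Off the default path (the retained variable sets are fixed); provided for
    exploratory re-analysis.  Returns a frame of subsets sorted by AUROC.
    """
    window = features["window"].iloc[0]
    if candidates is None:
        candidates = tuple(v for v in CANDIDATE_VARIABLES
                           if window == FIRST_WEEK or v != "n_distinct_active_days")
    rows = []
    for r in range(1, len(candidates) + 1):
        for subset in combinations(candidates, r):
            try:
                _, rep = fit_meu_model(features, labels, train_frac, seed, subset)
            except (ValueError, np.linalg.LinAlgError):
                continue
            rows.append({"variables": subset, "auroc": rep.auroc,
                         "sensitivity": rep.sensitivity,
                         "specificity": rep.specificity})
    return (pd.DataFrame(rows).sort_values("auroc", ascending=False)
            .reset_index(drop=True))
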