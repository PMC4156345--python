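from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ocsn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_year_sim():
    """Default calibrated two-year network, 2,000 users (clean, no artifacts)."""
    cfg = ocsn.SimConfig(seed=0)
    stream, truth = ocsn.simulate_network(cfg)
    return cfg, stream, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small clean network for fast structural tests."""
    cfg = ocsn.SimConfig(n_users=300, seed=3)
    stream, truth = ocsn.simulate_network(cfg)
    return cfg, stream, truth


def _year_block(year, n_users, n_posting, n_posts, n_comments, uid_prefix):
    """One year of activity: n_users active, the first n_posting of them make
    all posts (their first posts ever), everyone shares the comments."""
    users = np.array([f"{uid_prefix}{i:05d}" for i in range(n_users)])
    post_users = users[np.arange(n_posts) % n_posting]
    post_ids = np.array([f"{uid_prefix}p{i:06d}" for i in range(n_posts)])
    comment_users = users[np.arange(n_comments) % n_users]
    comment_threads = post_ids[np.arange(n_comments) % n_posts]
    ts_posts = pd.Timestamp(date(year, 1, 1)) + pd.to_timedelta(
        (np.arange(n_posts) % 360) * 86400 + 3600, unit="s")
    ts_comments = pd.Timestamp(date(year, 1, 1)) + pd.to_timedelta(
        (np.arange(n_comments) % 360) * 86400 + 7200, unit="s")
    posts = pd.DataFrame({
        "item_id": post_ids, "user_id": post_users, "timestamp": ts_posts,
        "kind": "post", "thread_id": post_ids,
        "text": [f"post {i}" for i in range(n_posts)],
    })
    comments = pd.DataFrame({
        "item_id": [f"{uid_prefix}c{i:06d}" for i in range(n_comments)],
        "user_id": comment_users, "timestamp": ts_comments,
        "kind": "comment", "thread_id": comment_threads,
        "text": [f"comment {i}" for i in range(n_comments)],
    })
    return pd.concat([posts, comments], ignore_index=True)


@pytest.fixture(scope="session")
def table1_stream():
    """A deterministic stream realising the benchmark annual totals.

    2011: 1,386 users (1,185 of them first-time posters), 6,536 posts,
    36,007 comments; 2012: 2,062 fresh users (1,730 posters), 12,043 posts,
    78,510 comments.  The user sets are disjoint across years, so each year's
    posters make their first posts ever that year.
    """
    a = _year_block(2011, 1386, 1185, 6536, 36007, "a")
    b = _year_block(2012, 2062, 1730, 12043, 78510, "b")
    df = pd.concat([a, b], ignore_index=True)
    return ocsn.make_interaction_set(df, date(2011, 1, 1), date(2012, 12, 31))
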