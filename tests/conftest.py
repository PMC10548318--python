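from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medema.synthetic import FOCUS_LEVELS, PRACTICE_TYPES


def make_stream(rng: np.random.Generator, user_id: int = 0, n: int | None = None,
                max_gap: int = 14, start_day: int = 0) -> pd.DataFrame:
    """Random minimal session stream with the documented schema."""
    if n is None:
        n = int(rng.integers(1, 26))
    gaps = rng.integers(1, max_gap + 1, size=n - 1) if n > 1 else np.array([], dtype=int)
    days = start_day + np.concatenate([[0], np.cumsum(gaps)])
    ts = pd.Timestamp("2021-06-01") + pd.to_timedelta(days, unit="D") \
        + pd.to_timedelta(rng.integers(0, 86400, size=n), unit="s")
    ts = ts.sort_values()
    return pd.DataFrame({
        "user_id": user_id,
        "session_index": np.arange(1, n + 1),
        "timestamp": ts,
        "mood": rng.integers(1, 6, size=n),
        "length_min": rng.uniform(3, 35, size=n),
        "practice_type": rng.choice(PRACTICE_TYPES, size=n),
        "worldview": "Other",
        "orientation": "Techniques",
        "focus": rng.choice(FOCUS_LEVELS, size=n),
        "content_tag": "none",
        "rating_score": 4.7,
        "rating_count": 1000,
        "play_count": 100000,
        "attributions": "",
        "time_of_day": rng.choice(["morning", "day", "night"], size=n),
    })


def stream_from_days(days, moods=None, user_id: int = 0, **overrides) -> pd.DataFrame:
    """Deterministic stream on given calendar days (ints)."""
    days = np.asarray(days)
    n = len(days)
    df = pd.DataFrame({
        "user_id": user_id,
        "session_index": np.arange(1, n + 1),
        "timestamp": pd.Timestamp("2021-06-01 10:00:00") + pd.to_timedelta(days, unit="D"),
        "mood": np.asarray(moods) if moods is not None else np.full(n, 3),
        "length_min": 10.0,
        "practice_type": "Mindfulness meditation",
        "worldview": "Other",
        "orientation": "Techniques",
        "focus": "interoceptive",
        "content_tag": "none",
        "rating_score": 4.7,
        "rating_count": 1000,
        "play_count": 100000,
        "attributions": "",
        "time_of_day": "morning",
    })
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210518)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    import medema as m

    cfg = m.SimConfig(n_users=60, mean_sessions_per_user=15, session_effect=0.01,
                      max_sessions=40, sleep_prob=0.03, children_prob=0.01, seed=11)
    users, sessions, truth = m.simulate_streams(cfg)
    return cfg, users, sessions, truth
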