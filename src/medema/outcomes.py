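"""Engineered well-being outcomes: equanimity, resilience, adherence.

Equanimity — even-minded stability of mood — is operationalized as the
rolling 5-session standard deviation of the ordinal mood, sign-flipped
(so larger = more equanimous) and min-max rescaled onto [1, 5] so it
lives on the same scale as the mood item itself.

Resilience is the number of sessions a user needs to return to (or
above) their previous week's average mood after dropping at least one
point below it; users who drop and never return are censored and
excluded from analysis.

Adherence is reaching a long-term session milestone (default >= 150
sessions, the top decile of typical usage), predicted from practice
habits in the first 30 sessions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as ft
from .synthetic import ConfigError

__all__ = [
    "EquanimitySeries",
    "ResilienceEvent",
    "rolling_mood_sd",
    "equanimity_series",
    "resilience_events",
    "resilience_event_table",
    "adherence_dataset",
]


@dataclass
class EquanimitySeries:
    """Per-session equanimity values for one user.

    ``raw`` holds the rolling-window sample SDs (NaN until the window is
    complete); ``value`` the sign-flipped, [1, 5]-rescaled series.
    """

    user_id: int
    raw: np.ndarray
    value: np.ndarray
    window: int


@dataclass
class ResilienceEvent:
    user_id: int
    drop_pos: int                 # 0-based position in the user's stream
    reference_mood: float         # trailing-week mean frozen at drop time
    sessions_to_recovery: int | None
    censored: bool


# ---------------------------------------------------------------------------
# Equanimity
# ---------------------------------------------------------------------------

def rolling_mood_sd(moods, window: int = 5) -> np.ndarray:
    """Rolling sample SD (n-1 denominator) of the trailing ``window``
    moods; NaN where fewer than ``window`` observations have accrued."""
    if window < 2:
        raise ConfigError(f"window must be >= 2, got {window!r}")
    s = pd.Series(np.asarray(moods, dtype=float))
    return s.rolling(window, min_periods=window).std(ddof=1).to_numpy()


def equanimity_series(
    streams: pd.DataFrame | dict[int, np.ndarray],
    window: int = 5,
    scope: str = "global",
) -> list[EquanimitySeries]:
    """Rolling-SD equanimity for every user, rescaled onto [1, 5].

    The raw rolling SDs are sign-flipped and min-max scaled over the
    corpus of defined values — globally across users by default
    (``scope="global"``), so scores are comparable between users; with
    ``scope="per_user"`` each user is scaled against their own range.
    The smallest observed SD maps to 5 (maximal equanimity), the largest
    to 1.  If all defined raw SDs are equal the scale is degenerate and
    every value maps to 5.
    """
    if scope not in ("global", "per_user"):
        raise ConfigError(f"scope must be 'global' or 'per_user', got {scope!r}")
    if isinstance(streams, pd.DataFrame):
        mood_by_user = {uid: grp["mood"].to_numpy() for uid, grp in streams.groupby("user_id", sort=True)}
    else:
        mood_by_user = streams

    raws = {uid: rolling_mood_sd(m, window) for uid, m in mood_by_user.items()}

    def _scale(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
        flipped = -raw
        if hi == lo:
            return np.where(np.isnan(raw), np.nan, 5.0)
        return 1.0 + 4.0 * (flipped - (-hi)) / (hi - lo)

    if scope == "global":
        pooled = np.concatenate([r for r in raws.values()]) if raws else np.array([])
        defined = pooled[~np.isnan(pooled)]
        if defined.size == 0:
            return [EquanimitySeries(uid, r, np.full_like(r, np.nan), window) for uid, r in raws.items()]
        lo, hi = float(defined.min()), float(defined.max())
        return [EquanimitySeries(uid, r, _scale(r, lo, hi), window) for uid, r in raws.items()]

    out = []
    for uid, r in raws.items():
        defined = r[~np.isnan(r)]
        if defined.size == 0:
            out.append(EquanimitySeries(uid, r, np.full_like(r, np.nan), window))
        else:
            out.append(EquanimitySeries(uid, r, _scale(r, float(defined.min()), float(defined.max())), window))
    return out


# ---------------------------------------------------------------------------
# Resilience
# ---------------------------------------------------------------------------

def resilience_events(
    sessions: pd.DataFrame,
    drop: float = 1.0,
    week: int = 7,
    freeze_reference: bool = True,
    include_current: bool = False,
) -> list[ResilienceEvent]:
    """Scan one user's sorted stream for mood-drop recovery events.

    An event opens at session i when its mood is at least ``drop`` points
    below the user's trailing-``week``-day average mood (excluding the
    current session by default — a drop should not dilute its own
    reference).  The reference is frozen at drop time; a counter then
    counts sessions until the first with mood >= reference.  Only one
    event can be active at a time, and an event still open when the
    stream ends is censored (the user may simply have churned).
    """
    ft._require_sorted(sessions)
    moods = sessions["mood"].to_numpy(dtype=float)
    days = ft._session_days(sessions)
    uid = sessions["user_id"].iloc[0] if len(sessions) else -1

    events: list[ResilienceEvent] = []
    active: ResilienceEvent | None = None
    counter = 0
    for i in range(len(moods)):
        if active is not None:
            counter += 1
            ref = active.reference_mood
            if not freeze_reference:
                ref = _trailing_mean(moods, days, i, week, include_current)
                if np.isnan(ref):
                    ref = active.reference_mood
            if moods[i] >= ref:
                active.sessions_to_recovery = counter
                active.censored = False
                events.append(active)
                active = None
            continue
        ref = _trailing_mean(moods, days, i, week, include_current)
        if np.isnan(ref):
            continue
        if moods[i] <= ref - drop:
            active = ResilienceEvent(uid, i, float(ref), None, True)
            counter = 0
    if active is not None:
        events.append(active)   # censored, excluded from analysis tables
    return events


def _trailing_mean(moods: np.ndarray, days: np.ndarray, i: int, week: int,
                   include_current: bool) -> float:
    """Mean mood of sessions in the trailing `week` days at position i.

    The window covers days (day_i - week, day_i]; the current session is
    excluded unless include_current is set.
    """
    upto = i + 1 if include_current else i
    sel = days[:upto] > days[i] - week
    if not sel.any():
        return np.nan
    return float(moods[:upto][sel].mean())


def resilience_event_table(
    sessions: pd.DataFrame,
    drop: float = 1.0,
    week: int = 7,
    include_censored: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Event table over all users; censored events excluded by default."""
    rows = []
    for _, grp in sessions.groupby("user_id", sort=True):
        grp = grp.reset_index(drop=True)
        for ev in resilience_events(grp, drop=drop, week=week, **kwargs):
            if ev.censored and not include_censored:
                continue
            rows.append({
                "user_id": ev.user_id,
                "drop_pos": ev.drop_pos,
                "session_count_at_drop": ev.drop_pos + 1,
                "reference_mood": ev.reference_mood,
                "sessions_to_recovery": ev.sessions_to_recovery,
                "censored": ev.censored,
            })
    return pd.DataFrame(rows, columns=[
        "user_id", "drop_pos", "session_count_at_drop", "reference_mood",
        "sessions_to_recovery", "censored",
    ])


# ---------------------------------------------------------------------------
# Adherence
# ---------------------------------------------------------------------------

def adherence_dataset(
    sessions: pd.DataFrame,
    users: pd.DataFrame | None = None,
    first_n: int = 30,
    threshold: int = 150,
    attrition: dict | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-user early-habit features with a long-term adherence label.

    Users with fewer than ``first_n`` sessions are excluded.  Features
    aggregate the first ``first_n`` sessions only (no leakage from later
    behaviour); the label — reached >= ``threshold`` total sessions — uses
    the full stream.  Returns ``(table, adherer_fraction)``.
    """
    if threshold <= first_n:
        raise ConfigError(
            f"threshold ({threshold}) must exceed first_n ({first_n})"
        )
    log = attrition if attrition is not None else {}
    totals = sessions.groupby("user_id", sort=True).size()
    log["users_in"] = int(len(totals))
    eligible = totals[totals >= first_n].index
    log["users_below_first_n"] = int((totals < first_n).sum())
    log["users_eligible"] = int(len(eligible))

    rows = []
    for uid in eligible:
        grp = sessions[sessions["user_id"] == uid].reset_index(drop=True)
        head = grp.iloc[:first_n]
        hab = ft.compute_habit_features(head)
        last = hab.iloc[-1]
        dpw_mean = float(hab["days_per_week"].mean())
        dsl_mean = float(hab["days_since_last"].iloc[1:].mean()) if first_n > 1 else np.nan
        rows.append({
            "user_id": uid,
            "n_first": int(len(head)),
            "baseline_mood": int(head["mood"].iloc[0]),
            "mean_mood": float(head["mood"].mean()),
            "dominant_time_of_day": head["time_of_day"].mode().iloc[0],
            "mean_days_per_week": dpw_mean,
            "mean_days_since_last": dsl_mean,
            "mean_length_min": float(head["length_min"].mean()),
            "extero_intero_ratio": float(last["extero_intero_ratio"]),
            "n_practice_types": int(last["n_practice_types"]),
            "total_sessions": int(totals.loc[uid]),
            "adherent": bool(totals.loc[uid] >= threshold),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["days_per_week_level"] = ft.factorize_days_per_week(
            np.clip(np.round(table["mean_days_per_week"]), 1, 7))
        table["days_since_last_level"] = ft.factorize_days_since_last(
            np.clip(np.round(table["mean_days_since_last"]), 1, 7), adherence=True)
        table["length_bin"] = ft.factorize_length(np.clip(table["mean_length_min"], 5, 30))
        table["practice_types_bin"] = ft.factorize_practice_types(table["n_practice_types"])
        table["ratio_level"] = ft.factorize_ratio(table["extero_intero_ratio"])
        if users is not None:
            table = table.merge(users, on="user_id", how="left", validate="one_to_one")
    frac = float(table["adherent"].mean()) if len(table) else float("nan")
    log["adherer_fraction"] = frac
    return table, frac
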