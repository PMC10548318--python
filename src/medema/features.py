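"""Session-stream feature engineering: practice periods, shifted outcomes,
habit features, outlier trimming and harmonization.

The central construction is the *practice period*: a maximal run of a
user's sessions with every consecutive inter-session gap <= 7 calendar
days.  Mood outcomes are shifted forward within a period (session j's
predictors are paired with session j+1's mood) and the period's first
mood is removed and kept as a baseline covariate, so that gaps longer
than a week never link a session to a mood it cannot plausibly predict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ConfigError

__all__ = [
    "PracticePeriod",
    "DEFAULT_GAP_DAYS",
    "DAYS_PER_WEEK_LEVELS",
    "DAYS_SINCE_LAST_LEVELS",
    "DAYS_SINCE_LAST_ADHERENCE_LEVELS",
    "LENGTH_BIN_LEVELS",
    "PRACTICE_TYPES_BIN_LEVELS",
    "filter_content",
    "segment_practice_periods",
    "shift_outcomes",
    "compute_habit_features",
    "trim_outliers",
    "harmonize",
    "factorize_days_per_week",
    "factorize_days_since_last",
    "factorize_length",
    "factorize_practice_types",
    "factorize_ratio",
    "build_feature_table",
]

DEFAULT_GAP_DAYS = 7

# habit-variable level sets used by the stratified nonlinear models and the
# adherence model (coarse high ends keep every level well populated)
DAYS_PER_WEEK_LEVELS = ("1", "2", "3", "4-7")
DAYS_SINCE_LAST_LEVELS = ("1", "2", "3-7")
DAYS_SINCE_LAST_ADHERENCE_LEVELS = ("1", "2", "3-4", "5-7")
LENGTH_BIN_LEVELS = ("5-10", "11-20", "21-30")
PRACTICE_TYPES_BIN_LEVELS = ("1-4", "5-8", "9-12")


@dataclass
class PracticePeriod:
    """A maximal run of one user's sessions with all gaps <= ``gap_days``."""

    user_id: int
    period_index: int                     # 1-based
    session_indices: list[int] = field(default_factory=list)  # positions in the user's stream (0-based)
    baseline_mood: int = 0                # first session's mood in the period
    days_since_previous_period: float | None = None


def _session_days(sessions: pd.DataFrame) -> np.ndarray:
    """Calendar day of each session as integer days since epoch."""
    ts = pd.to_datetime(sessions["timestamp"])
    return ts.to_numpy().astype("datetime64[D]").astype(np.int64)


def _require_sorted(sessions: pd.DataFrame) -> None:
    ts = pd.to_datetime(sessions["timestamp"]).to_numpy()
    if len(ts) > 1 and (np.diff(ts) < np.timedelta64(0)).any():
        raise ValueError("sessions must be sorted by timestamp within user")


def filter_content(sessions: pd.DataFrame, exclude: tuple[str, ...] = ("children", "sleep")) -> pd.DataFrame:
    """Drop children-related and sleep meditations before any feature
    computation (a child may have done the session; sleep sessions have an
    unverifiable effective length)."""
    if "content_tag" not in sessions.columns:
        return sessions
    return sessions[~sessions["content_tag"].isin(exclude)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Practice periods and shifted outcomes
# ---------------------------------------------------------------------------

def segment_practice_periods(sessions: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS) -> list[PracticePeriod]:
    """Split one user's sorted sessions into maximal practice periods.

    A calendar-day gap of exactly ``gap_days`` stays within a period
    ("no longer than" semantics); a gap greater than ``gap_days`` starts a
    new one.
    """
    if gap_days < 1:
        raise ConfigError(f"gap_days must be >= 1, got {gap_days!r}")
    if len(sessions) == 0:
        return []
    uid = sessions["user_id"].iloc[0]
    _require_sorted(sessions)
    days = _session_days(sessions)
    gaps = np.diff(days)

    periods: list[PracticePeriod] = []
    start = 0
    boundaries = list(np.nonzero(gaps > gap_days)[0] + 1) + [len(days)]
    prev_end_day: float | None = None
    for k, stop in enumerate(boundaries, start=1):
        periods.append(PracticePeriod(
            user_id=uid,
            period_index=k,
            session_indices=list(range(start, stop)),
            baseline_mood=int(sessions["mood"].iloc[start]),
            days_since_previous_period=(
                None if prev_end_day is None else float(days[start] - prev_end_day)
            ),
        ))
        prev_end_day = days[stop - 1]
        start = stop
    return periods


def shift_outcomes(period: PracticePeriod, sessions: pd.DataFrame) -> pd.DataFrame:
    """Forward-shift moods within one practice period.

    A period of k sessions yields k-1 rows: row j carries session j's
    predictors (via ``predictor_pos``) and session j+1's mood as
    ``outcome_mood``.  The period's first mood is the baseline covariate;
    the first session contributes no outcome row of its own.
    """
    if len(period.session_indices) == 0:
        raise ValueError("period must contain at least one session")
    pos = period.session_indices
    if len(pos) == 1:
        return pd.DataFrame(columns=[
            "user_id", "period_index", "predictor_pos", "outcome_pos",
            "outcome_mood", "baseline_mood", "days_since_previous_period",
        ])
    moods = sessions["mood"].to_numpy()
    return pd.DataFrame({
        "user_id": period.user_id,
        "period_index": period.period_index,
        "predictor_pos": pos[:-1],
        "outcome_pos": pos[1:],
        "outcome_mood": moods[pos[1:]].astype(int),
        "baseline_mood": period.baseline_mood,
        "days_since_previous_period": (
            np.nan if period.days_since_previous_period is None
            else period.days_since_previous_period
        ),
    })


# ---------------------------------------------------------------------------
# Habit features
# ---------------------------------------------------------------------------

def _habit_features_multi(sessions: pd.DataFrame, week_window: int = 7) -> pd.DataFrame:
    """Vectorized habit features over a user-blocked, time-sorted frame."""
    n = len(sessions)
    uid = sessions["user_id"].to_numpy()
    days = _session_days(sessions)
    new_user = np.concatenate([[True], uid[1:] != uid[:-1]]) if n else np.array([], bool)
    start_idx = np.maximum.accumulate(np.where(new_user, np.arange(n), 0))

    session_count = np.arange(n) - start_idx + 1
    days_since_last = np.concatenate([[np.nan], np.diff(days).astype(float)]) if n else np.array([])
    days_since_last[new_user] = np.nan

    # distinct meditated days in the trailing window: within a sorted user
    # block, distinct(lo..i) = F[i] - F[lo] + 1 with F counting first
    # occurrences; a user-offset key keeps searchsorted inside the block
    firstocc = new_user | np.concatenate([[False], days[1:] != days[:-1]]) if n else new_user
    F = np.cumsum(firstocc)
    ucodes = pd.factorize(uid)[0]   # order of appearance keeps the key sorted
    span = (days.max() - days.min() + week_window + 2) if n else 1
    key = ucodes.astype(np.int64) * (2 * span) + (days - (days.min() if n else 0))
    lo_idx = np.searchsorted(key, key - (week_window - 1), side="left")
    dpw = F - F[lo_idx] + 1

    def within_cumsum(x: np.ndarray) -> np.ndarray:
        c = np.cumsum(x)
        offset = c[start_idx] - x[start_idx]
        return c - offset

    focus = sessions["focus"].to_numpy()
    cum_ext = within_cumsum((focus == "exteroceptive").astype(np.int64))
    cum_int = within_cumsum((focus == "interoceptive").astype(np.int64))
    ratio = np.where(cum_int > 0, cum_ext / np.maximum(cum_int, 1), np.nan)

    new_type = (~sessions.duplicated(["user_id", "practice_type"])).to_numpy()
    n_types = within_cumsum(new_type.astype(np.int64))

    return pd.DataFrame({
        "session_count": session_count,
        "days_since_last": days_since_last,
        "days_per_week": dpw,
        "extero_intero_ratio": ratio,
        "n_practice_types": n_types,
    }, index=sessions.index)


def compute_habit_features(sessions: pd.DataFrame, week_window: int = 7) -> pd.DataFrame:
    """Per-session dose / habit predictors for one user's sorted stream.

    Columns: ``session_count`` (cumulative), ``days_since_last`` (calendar
    days to the previous session, NaN for the first),
    ``days_per_week`` (distinct meditated days in the trailing
    ``week_window`` days, inclusive of the current day),
    ``extero_intero_ratio`` (cumulative exteroceptive / interoceptive
    count; NaN while the interoceptive count is zero), and
    ``n_practice_types`` (running count of distinct practice types).
    """
    _require_sorted(sessions)
    return _habit_features_multi(sessions, week_window=week_window)


# ---------------------------------------------------------------------------
# Trimming and harmonization
# ---------------------------------------------------------------------------

def trim_outliers(values, k: float = 1.5, interpolation: str = "linear") -> np.ndarray:
    """Box-plot (Tukey-fence) keep-mask: True where

        Q1 - k*IQR <= value <= Q3 + k*IQR.

    Quartiles use ``numpy.nanquantile`` with the given interpolation
    (default ``linear``, the convention of most plotting software).
    NaNs are kept (they carry their own missingness semantics).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be nonempty")
    q1, q3 = np.nanquantile(x, [0.25, 0.75], method=interpolation)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return np.isnan(x) | ((x >= lo) & (x <= hi))


def harmonize(values, width: float = 5.0) -> np.ndarray:
    """Map each value to the nearest multiple of ``width``; exact ties
    round away from zero (12.5 -> 15 with width 5)."""
    if width <= 0:
        raise ConfigError(f"width must be > 0, got {width!r}")
    x = np.asarray(values, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) / width + 0.5) * width


# ---------------------------------------------------------------------------
# Habit-level factorization (level sets of the stratified nonlinear and
# adherence models)
# ---------------------------------------------------------------------------

def _cut(values, edges: list[float], labels: tuple[str, ...]) -> pd.Categorical:
    return pd.cut(np.asarray(values, dtype=float), bins=edges, labels=list(labels),
                  include_lowest=True, right=True)


def factorize_days_per_week(values) -> pd.Categorical:
    return _cut(values, [0.5, 1.5, 2.5, 3.5, 7.5], DAYS_PER_WEEK_LEVELS)


def factorize_days_since_last(values, adherence: bool = False) -> pd.Categorical:
    if adherence:
        return _cut(values, [0.5, 1.5, 2.5, 4.5, 7.5], DAYS_SINCE_LAST_ADHERENCE_LEVELS)
    return _cut(values, [0.5, 1.5, 2.5, 7.5], DAYS_SINCE_LAST_LEVELS)


def factorize_length(values) -> pd.Categorical:
    return _cut(values, [4.5, 10.5, 20.5, 30.5], LENGTH_BIN_LEVELS)


def factorize_practice_types(values) -> pd.Categorical:
    return _cut(values, [0.5, 4.5, 8.5, 12.5], PRACTICE_TYPES_BIN_LEVELS)


def factorize_ratio(values, max_level: int = 9) -> pd.Categorical:
    """Exteroceptive:interoceptive ratio levels 0:1 ... ``max_level``:1
    (nearest integer, capped)."""
    x = np.asarray(values, dtype=float)
    lev = np.floor(x + 0.5)
    lev = np.clip(lev, 0, max_level)
    labels = [f"{k}:1" for k in range(max_level + 1)]
    out = np.full(len(x), None, dtype=object)
    ok = ~np.isnan(x)
    out[ok] = [labels[int(v)] for v in lev[ok]]
    return pd.Categorical(out, categories=labels)


# ---------------------------------------------------------------------------
# Model-ready feature table
# ---------------------------------------------------------------------------

def build_feature_table(
    sessions: pd.DataFrame,
    users: pd.DataFrame,
    gap_days: int = DEFAULT_GAP_DAYS,
    bin_width: float = 5.0,
    week_window: int = 7,
    trim: bool = True,
    content_filter: bool = True,
    attrition: dict | None = None,
) -> pd.DataFrame:
    """Assemble the model-ready table of within-period shifted outcomes.

    Steps, in order: content filter (children/sleep), per-user habit
    features, practice-period segmentation, forward shift, covariate join,
    box-plot trimming of session counts and lengths, harmonization to the
    nearest ``bin_width`` sessions / minutes, habit-level factorization.

    ``attrition``, if given, is filled with row counts entering/leaving
    each filter so cohort attrition is auditable.
    """
    log = attrition if attrition is not None else {}
    log["sessions_in"] = int(len(sessions))
    if content_filter:
        sessions = filter_content(sessions)
    log["sessions_after_content_filter"] = int(len(sessions))
    log["content_filter_removed"] = log["sessions_in"] - log["sessions_after_content_filter"]

    sessions = sessions.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
    n = len(sessions)
    if n == 0:
        raise ValueError("no sessions left after filtering")
    uid = sessions["user_id"].to_numpy()
    days = _session_days(sessions)
    mood = sessions["mood"].to_numpy()
    new_user = np.concatenate([[True], uid[1:] != uid[:-1]])
    gap_row = np.concatenate([[np.nan], np.diff(days).astype(float)])
    gap_row[new_user] = np.nan

    # vectorized practice-period segmentation over all users at once
    new_period = new_user | (gap_row > gap_days)
    period_global = np.cumsum(new_period)                       # 1-based period id
    user_start = np.maximum.accumulate(np.where(new_user, np.arange(n), 0))
    period_index = period_global - period_global[user_start] + 1
    baseline_by_period = mood[new_period]
    baseline_row = baseline_by_period[period_global - 1]
    dspp_by_period = gap_row[new_period]                        # NaN for a user's first period
    dspp_row = dspp_by_period[period_global - 1]

    hab = _habit_features_multi(sessions, week_window=week_window)

    # shifted outcomes: row i is a predictor iff row i+1 is in the same period
    pred_mask = np.concatenate([period_global[1:] == period_global[:-1], [False]])
    pred_pos = np.nonzero(pred_mask)[0]
    out_pos = pred_pos + 1

    table = sessions.loc[pred_pos, [
        "user_id", "session_index", "timestamp", "mood", "length_min", "practice_type",
        "worldview", "orientation", "focus", "rating_score", "rating_count",
        "play_count", "attributions", "time_of_day",
    ]].rename(columns={"mood": "predictor_mood", "timestamp": "predictor_timestamp"}
              ).reset_index(drop=True)
    table.insert(1, "period_index", period_index[pred_pos])
    table["outcome_mood"] = mood[out_pos].astype(int)
    table["outcome_timestamp"] = pd.to_datetime(sessions["timestamp"]).to_numpy()[out_pos]
    table["baseline_mood"] = baseline_row[pred_pos]
    table["days_since_previous_period"] = dspp_row[pred_pos]
    table = pd.concat([table, hab.loc[pred_pos].reset_index(drop=True)], axis=1)
    if len(table) == 0:
        raise ValueError("no within-period transitions: every period has a single session")
    log["feature_rows"] = int(len(table))

    table = table.merge(users, on="user_id", how="left", validate="many_to_one")

    if trim:
        keep = trim_outliers(table["session_count"]) & trim_outliers(table["length_min"])
        log["trim_removed"] = int((~keep).sum())
        table = table[keep].reset_index(drop=True)
    else:
        log["trim_removed"] = 0
    log["rows_after_trim"] = int(len(table))

    table["session_count_5"] = harmonize(table["session_count"], bin_width)
    table["length_min_5"] = harmonize(table["length_min"], bin_width)
    table["ratio_missing"] = table["extero_intero_ratio"].isna()

    table["days_per_week_level"] = factorize_days_per_week(table["days_per_week"])
    table["days_since_last_level"] = factorize_days_since_last(table["days_since_last"])
    table["length_bin"] = factorize_length(np.clip(table["length_min"], 5, 30))
    table["practice_types_bin"] = factorize_practice_types(table["n_practice_types"])
    table["ratio_level"] = factorize_ratio(table["extero_intero_ratio"])
    return table
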