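"""Synthetic EMA session-stream generator with known ground truth.

Emulates the data structure of a meditation app's per-session mood
check-in ("How are you today?", 5 ordered categories), so that every
downstream stage — practice-period segmentation, habit features,
equanimity / resilience / adherence outcomes, and the model fits — can
be validated against injected effects without any external data.

Data-generating process
-----------------------
Each user has a latent mood trajectory

    latent[i] = baseline + session_effect * (i - 1)
                + consistency_effect * days_per_week[i]
                + profile(i) + noise,   noise ~ N(0, noise_sd)

with ``i`` the 1-based session index and ``days_per_week`` the number of
distinct meditated calendar days in the trailing 7 days (inclusive of
the session's day).  The ordinal mood is obtained by thresholding the
latent value at four fixed global cutpoints:

    mood = 1 + #{cutpoints strictly below latent}

Inter-session gaps are drawn from a truncated geometric distribution on
{1, ..., 14} days whose default success probability puts ~90% of gaps at
<= 7 days.  Churn is an absorbing per-session dropout with hazard ``h``,
so (uncapped) per-user session counts are geometric with mean ``1/h``.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` children (stream splitting), so each stage
can be regenerated in isolation and seeded runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "ConfigError",
    "CONTINENTS",
    "PRACTICE_TYPES",
    "WORLDVIEWS",
    "ORIENTATIONS",
    "FOCUS_LEVELS",
    "generate_users",
    "generate_sessions",
    "simulate_streams",
    "expected_mood",
    "implied_session_slope",
    "simulate_adherence_cohort",
    "save_simulation",
    "load_simulation",
]


class ConfigError(ValueError):
    """Invalid simulation / pipeline configuration; names the bad field."""


# ---------------------------------------------------------------------------
# Categorical vocabularies (continent marginals follow the cohort schema of
# a large international meditation-app sample; the remaining category lists
# follow the app's content taxonomy).
# ---------------------------------------------------------------------------

CONTINENTS = (
    "Africa",
    "Asia",
    "Australia and Oceania",
    "Europe",
    "North America",
    "South America",
)
CONTINENT_PROBS = (0.0149, 0.038, 0.0943, 0.2189, 0.601, 0.0329)

PRACTICE_TYPES = (
    "Alternative",
    "Body scan",
    "Breathing meditation",
    "Compassion meditation",
    "Contemplation",
    "Guided imagery",
    "Loving-kindness (metta)",
    "MBCT or MBSR",
    "Mindfulness meditation",
    "Positive affirmations",
    "Relaxation meditation",
    "Vipassana",
)
PRACTICE_TYPE_PROBS = (
    0.524, 0.039, 0.065, 0.018, 0.027, 0.094,
    0.008, 0.006, 0.148, 0.046, 0.013, 0.012,
)

WORLDVIEWS = ("Buddhism", "Christianity", "Modernism", "Niches", "Other")
WORLDVIEW_PROBS = (0.078, 0.009, 0.266, 0.127, 0.520)

ORIENTATIONS = ("Niches", "Positivity based", "Problem focused", "Techniques")
ORIENTATION_PROBS = (0.256, 0.301, 0.319, 0.124)

FOCUS_LEVELS = ("interoceptive", "exteroceptive", "other")

REASONS = ("anxiety", "stress", "sadness", "well_being")
REASON_PROBS = (0.684, 0.653, 0.367, 0.632)

EXPERIENCE_TYPES = (
    "local_class", "apps", "mentoring", "none", "web_course", "retreats",
)
EXPERIENCE_PROBS = (0.280, 0.700, 0.143, 0.195, 0.236, 0.140)

ATTRIBUTION_TAGS = ("work", "family", "health", "sleep_quality", "world_events")

TIME_OF_DAY_LEVELS = ("morning", "day", "night")

#: content tags used by the children/sleep exclusion filter
CONTENT_TAGS = ("none", "sleep", "children")

_EPOCH = np.datetime64("2021-05-18")


def _truncated_geometric_pmf(p: float, support_max: int) -> np.ndarray:
    k = np.arange(1, support_max + 1)
    pmf = p * (1.0 - p) ** (k - 1)
    return pmf / pmf.sum()


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic session-stream generator.

    Effects (``session_effect``, ``consistency_effect``,
    ``nonlinear_profile``) are in latent-mood units; ``ordinal_cutpoints``
    map the latent scale onto the 5 ordered mood categories.
    """

    n_users: int = 100
    mean_sessions_per_user: int = 20
    session_effect: float = 0.0
    consistency_effect: float = 0.0
    nonlinear_profile: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None
    noise_sd: float = 0.6
    churn_hazard: float | None = None     # default: 1 / mean_sessions_per_user
    max_sessions: int = 300
    gap_p: float = 0.28                   # truncated-geometric success prob
    gap_max: int = 14                     # gap support {1, ..., gap_max} days
    ordinal_cutpoints: tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)
    baseline_latent_sd: float = 0.3
    baseline_latent_mean: float = 0.0
    age_mean: float = 37.5
    age_sd: float = 12.6
    mean_length_min: float = 11.5
    focus_probs: tuple[float, float, float] = (0.55, 0.35, 0.10)
    sleep_prob: float = 0.0               # content_tag marginals (filter tests
    children_prob: float = 0.0            # switch these on)
    start_window_days: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_users", "mean_sessions_per_user", "max_sessions", "gap_max"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.churn_hazard is not None and not (0.0 <= self.churn_hazard <= 1.0):
            raise ConfigError(f"churn_hazard must be in [0, 1], got {self.churn_hazard!r}")
        if not (0.0 < self.gap_p <= 1.0):
            raise ConfigError(f"gap_p must be in (0, 1], got {self.gap_p!r}")
        cuts = tuple(self.ordinal_cutpoints)
        if len(cuts) != 4 or not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ConfigError(
                f"ordinal_cutpoints must be 4 strictly ascending values, got {cuts!r}"
            )
        if self.baseline_latent_sd < 0:
            raise ConfigError("baseline_latent_sd must be >= 0")
        probs = self.focus_probs
        if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ConfigError(f"focus_probs must be 3 nonnegative values summing to 1, got {probs!r}")
        for name in ("sleep_prob", "children_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")

    @property
    def hazard(self) -> float:
        return self.churn_hazard if self.churn_hazard is not None else 1.0 / self.mean_sessions_per_user

    def profile_offsets(self, indices: np.ndarray) -> np.ndarray:
        """Latent offset of the nonlinear dose-response profile at 1-based
        session indices; tabulated profiles extend with their last value."""
        if self.nonlinear_profile is None:
            return np.zeros(len(indices), dtype=float)
        if callable(self.nonlinear_profile):
            return np.asarray(self.nonlinear_profile(np.asarray(indices)), dtype=float)
        table = np.asarray(self.nonlinear_profile, dtype=float)
        idx = np.clip(np.asarray(indices, dtype=int) - 1, 0, len(table) - 1)
        return table[idx]

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """Named child generators split off the root seed.

    Spawn order is fixed (users, counts, gaps, latent, content), so each
    stage draws from its own stream and stages can be regenerated in
    isolation without disturbing the others.
    """
    root = np.random.SeedSequence(config.seed)
    names = ("users", "counts", "gaps", "latent", "content")
    return {name: np.random.default_rng(child) for name, child in zip(names, root.spawn(len(names)))}


# ---------------------------------------------------------------------------
# Users
# ---------------------------------------------------------------------------

def generate_users(config: SimConfig) -> pd.DataFrame:
    """Draw onboarding profiles: continent, age (truncated at 18 per the
    adults-only inclusion rule), reasons for meditating, prior experience,
    and the user's latent baseline mood."""
    config.validate()
    rng = _streams(config)["users"]
    n = config.n_users

    continent = rng.choice(CONTINENTS, size=n, p=np.asarray(CONTINENT_PROBS) / sum(CONTINENT_PROBS))
    # ages: normal truncated below at 18
    a = (18.0 - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    users = pd.DataFrame({
        "user_id": np.arange(n, dtype=int),
        "continent": continent,
        "age": age,
        "baseline_latent": config.baseline_latent_mean
        + config.baseline_latent_sd * rng.standard_normal(n),
    })
    for reason, p in zip(REASONS, REASON_PROBS):
        users[f"reason_{reason}"] = rng.random(n) < p
    for exp, p in zip(EXPERIENCE_TYPES, EXPERIENCE_PROBS):
        users[f"experience_{exp}"] = rng.random(n) < p
    return users


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def expected_mood(mu: np.ndarray | float, cutpoints: Sequence[float], noise_sd: float) -> np.ndarray | float:
    """E[ordinal mood] under the latent-Gaussian threshold model.

    ``mu`` is the systematic latent mood; the expectation integrates over
    the N(0, noise_sd) latent noise.  With noise_sd == 0 this reduces to
    the deterministic threshold map ``1 + #{cutpoints < mu}``.
    """
    mu = np.asarray(mu, dtype=float)
    cuts = np.asarray(cutpoints, dtype=float)
    if noise_sd == 0:
        return 1.0 + (mu[..., None] > cuts).sum(axis=-1).astype(float)
    z = (mu[..., None] - cuts) / noise_sd
    return 1.0 + stats.norm.cdf(z).sum(axis=-1)


def generate_sessions(
    users: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate each user's session stream until churn or the session cap.

    Returns ``(sessions, truth)``: the observable session table and the
    ground-truth table (latent values, systematic part, expected mood)
    joined 1:1 on ``(user_id, session_index)``.
    """
    config.validate()
    if len(users) == 0:
        raise ConfigError("users must be nonempty")
    streams = _streams(config)
    rng_counts, rng_gaps = streams["counts"], streams["gaps"]
    rng_latent, rng_content = streams["latent"], streams["content"]

    hazard = config.hazard
    gap_pmf = _truncated_geometric_pmf(config.gap_p, config.gap_max)
    gap_support = np.arange(1, config.gap_max + 1)
    n_users = len(users)

    # geometric session counts (absorbing churn), capped
    if hazard > 0:
        counts = rng_counts.geometric(hazard, size=n_users)
    else:
        counts = np.full(n_users, config.max_sessions)
    counts = np.minimum(counts, config.max_sessions)
    start_days = rng_gaps.integers(0, config.start_window_days, size=n_users)

    # flat layout: one row per session, users in blocks
    total = int(counts.sum())
    uid = np.repeat(users["user_id"].to_numpy(), counts)
    base = np.repeat(users["baseline_latent"].to_numpy(), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pos = np.arange(total)
    sidx = pos - np.repeat(starts, counts) + 1                 # 1-based index

    gaps = rng_gaps.choice(gap_support, size=total, p=gap_pmf)
    gaps[starts] = 0
    day = np.cumsum(gaps)
    day = day - np.repeat(day[starts], counts) + np.repeat(start_days, counts)

    # trailing days/week via within-user searchsorted on an offset key
    span = int(day.max() - day.min()) + 9
    key = np.repeat(np.arange(n_users, dtype=np.int64), counts) * (2 * span) + (day - day.min())
    lo_idx = np.searchsorted(key, key - 6, side="left")
    dpw = pos - lo_idx + 1                                     # gaps >= 1 day: all days distinct

    profile = config.profile_offsets(sidx)
    systematic = (
        base
        + config.session_effect * (sidx - 1)
        + config.consistency_effect * dpw
        + profile
    )
    latent = systematic + config.noise_sd * rng_latent.standard_normal(total)
    cuts = np.asarray(config.ordinal_cutpoints)
    mood = 1 + (latent[:, None] > cuts).sum(axis=1)

    seconds = rng_content.integers(5 * 3600, 24 * 3600, size=total)
    ts = (
        _EPOCH.astype("datetime64[s]")
        + day.astype("timedelta64[D]").astype("timedelta64[s]")
        + seconds.astype("timedelta64[s]")
    )
    hour = seconds // 3600
    tod = np.where(hour < 11, "morning", np.where(hour < 18, "day", "night"))

    length = np.maximum(1.0, rng_content.gamma(8.0, config.mean_length_min / 8.0, size=total))
    focus = rng_content.choice(FOCUS_LEVELS, size=total, p=config.focus_probs)
    tag_draw = rng_content.random(total)
    content_tag = np.where(
        tag_draw < config.sleep_prob, "sleep",
        np.where(tag_draw < config.sleep_prob + config.children_prob, "children", "none"),
    )
    present = rng_content.random((total, len(ATTRIBUTION_TAGS))) < 0.25
    attributions = ["|".join(t for t, keep in zip(ATTRIBUTION_TAGS, row) if keep)
                    for row in present]

    sessions = pd.DataFrame({
        "user_id": uid,
        "session_index": sidx,
        "timestamp": ts,
        "mood": mood.astype(int),
        "length_min": length,
        "practice_type": rng_content.choice(PRACTICE_TYPES, size=total, p=PRACTICE_TYPE_PROBS),
        "worldview": rng_content.choice(WORLDVIEWS, size=total, p=WORLDVIEW_PROBS),
        "orientation": rng_content.choice(ORIENTATIONS, size=total, p=ORIENTATION_PROBS),
        "focus": focus,
        "content_tag": content_tag,
        "rating_score": np.clip(4.72 + 0.12 * rng_content.standard_normal(total), 1, 5),
        "rating_count": np.exp(rng_content.normal(11.0, 1.0, size=total)).astype(int),
        "play_count": np.exp(rng_content.normal(14.0, 1.2, size=total)).astype(int),
        "attributions": attributions,
        "time_of_day": tod,
    })
    truth = pd.DataFrame({
        "user_id": uid,
        "session_index": sidx,
        "latent": latent,
        "latent_systematic": systematic,
        "expected_mood": expected_mood(systematic, cuts, config.noise_sd),
        "days_per_week": dpw,
        "profile_offset": profile,
    })
    return sessions, truth


def simulate_streams(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: ``(users, sessions, truth)`` for one config."""
    users = generate_users(config)
    sessions, truth = generate_sessions(users, config)
    return users, sessions, truth


# ---------------------------------------------------------------------------
# Model-scale truth helpers
# ---------------------------------------------------------------------------

def implied_session_slope(config: SimConfig, n_users: int = 20000, n_sessions: int = 25) -> float:
    """Within-user slope of expected ordinal mood per session index.

    The generator injects ``session_effect`` in latent units; fitted models
    see the ordinal scale, where the threshold map compresses or expands
    the effect.  This returns the population (noise-free) within-user OLS
    slope of E[mood] on session index, integrating over the baseline
    distribution — the estimand a random-intercept linear model targets.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x51))
                                .generate_state(1)[0])
    baselines = config.baseline_latent_mean + config.baseline_latent_sd * rng.standard_normal(n_users)
    sidx = np.arange(1, n_sessions + 1, dtype=float)
    mu = baselines[:, None] + config.session_effect * (sidx - 1) + config.profile_offsets(sidx.astype(int))
    em = expected_mood(mu, config.ordinal_cutpoints, config.noise_sd)
    y = em - em.mean(axis=1, keepdims=True)
    x = sidx - sidx.mean()
    return float((y * x).sum() / (n_users * (x * x).sum()))


# ---------------------------------------------------------------------------
# Direct adherence cohort (logistic ground truth)
# ---------------------------------------------------------------------------

def simulate_adherence_cohort(
    n_users: int,
    *,
    intercept: float = -1.8,
    days_per_week_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort whose adherence labels follow a known logistic model.

    Habit-level factors are drawn independently; the log-odds of reaching
    the long-term session milestone are ``intercept`` plus the effect of
    the user's days-per-week level (reference level "1").  Used for
    odds-ratio parameter-recovery studies where the generative logit must
    be known exactly.
    """
    if days_per_week_effects is None:
        days_per_week_effects = {"2": 0.2, "3": 0.4, "4-7": np.log(2.0)}
    rng = np.random.default_rng(seed)
    levels = ["1", "2", "3", "4-7"]
    dpw = rng.choice(levels, size=n_users, p=[0.4, 0.25, 0.15, 0.2])
    length_bin = rng.choice(["5-10", "11-20", "21-30"], size=n_users, p=[0.45, 0.4, 0.15])
    types_bin = rng.choice(["1-4", "5-8", "9-12"], size=n_users, p=[0.55, 0.35, 0.10])
    baseline_mood = rng.integers(2, 5, size=n_users)
    logit = intercept + np.array([days_per_week_effects.get(v, 0.0) for v in dpw])
    p = 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame({
        "user_id": np.arange(n_users),
        "days_per_week_level": pd.Categorical(dpw, categories=levels),
        "length_bin": pd.Categorical(length_bin, categories=["5-10", "11-20", "21-30"]),
        "practice_types_bin": pd.Categorical(types_bin, categories=["1-4", "5-8", "9-12"]),
        "baseline_mood": baseline_mood,
        "adherent": rng.random(n_users) < p,
    })


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_simulation(out_dir, users: pd.DataFrame, sessions: pd.DataFrame,
                    truth: pd.DataFrame) -> None:
    """Write users.csv, sessions.csv and truth.csv (documented headers)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    users.to_csv(out / "users.csv", index=False)
    sessions.to_csv(out / "sessions.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)


def load_simulation(in_dir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read the CSVs written by :func:`save_simulation`; truth is optional."""
    from pathlib import Path

    p = Path(in_dir)
    users = pd.read_csv(p / "users.csv")
    sessions = pd.read_csv(p / "sessions.csv", parse_dates=["timestamp"])
    sessions["attributions"] = sessions["attributions"].fillna("")
    truth_path = p / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return users, sessions, truth
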