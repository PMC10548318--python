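"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (linear scans, O(n^2) recomputes,
textbook formulas) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_segment(days: list[int], gap_days: int = 7) -> list[list[int]]:
    """Linear scan: start a new period whenever the gap exceeds the threshold."""
    if not days:
        return []
    parts = [[0]]
    for i in range(1, len(days)):
        if days[i] - days[i - 1] > gap_days:
            parts.append([i])
        else:
            parts[-1].append(i)
    return parts


def brute_habits(days: list[int], focus: list[str], ptypes: list[str],
                 week_window: int = 7) -> dict:
    """Recompute every habit feature from scratch at every index."""
    n = len(days)
    out = {"session_count": [], "days_since_last": [], "days_per_week": [],
           "extero_intero_ratio": [], "n_practice_types": []}
    for i in range(n):
        out["session_count"].append(i + 1)
        out["days_since_last"].append(float("nan") if i == 0 else float(days[i] - days[i - 1]))
        window_days = {days[j] for j in range(i + 1)
                       if days[i] - (week_window - 1) <= days[j] <= days[i]}
        out["days_per_week"].append(len(window_days))
        n_ext = sum(1 for j in range(i + 1) if focus[j] == "exteroceptive")
        n_int = sum(1 for j in range(i + 1) if focus[j] == "interoceptive")
        out["extero_intero_ratio"].append(n_ext / n_int if n_int > 0 else float("nan"))
        out["n_practice_types"].append(len({ptypes[j] for j in range(i + 1)}))
    return out


def brute_rolling_sd(moods: list[float], window: int = 5) -> list[float]:
    """Sample SD of each complete trailing window, by the direct formula."""
    out = []
    for i in range(len(moods)):
        if i + 1 < window:
            out.append(float("nan"))
            continue
        w = moods[i + 1 - window: i + 1]
        mean = sum(w) / window
        out.append(math.sqrt(sum((v - mean) ** 2 for v in w) / (window - 1)))
    return out


def brute_resilience(moods: list[float], days: list[int], drop: float = 1.0,
                     week: int = 7) -> list[tuple[int, float, int | None, bool]]:
    """Scan for drop events, recomputing the trailing-week mean at every
    index; returns (drop_index, reference, sessions_to_recovery, censored)."""
    events = []
    i = 0
    n = len(moods)
    while i < n:
        prior = [moods[j] for j in range(i) if days[j] > days[i] - week]
        if prior and moods[i] <= (sum(prior) / len(prior)) - drop:
            ref = sum(prior) / len(prior)
            j = i + 1
            counter = 0
            recovered = None
            while j < n:
                counter += 1
                if moods[j] >= ref:
                    recovered = counter
                    break
                j += 1
            if recovered is None:
                events.append((i, ref, None, True))
                break
            events.append((i, ref, recovered, False))
            i = j + 1
        else:
            i += 1
    return events


def brute_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(1.0, pvalues[i] * m / rank_from_end)
        running_min = min(running_min, val)
        q[i] = running_min
    return q


def brute_quartile_mask(values: list[float], k: float = 1.5) -> list[bool]:
    """Direct quartile computation (linear interpolation) and Tukey fences."""
    x = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    return [(q1 - k * iqr) <= v <= (q3 + k * iqr) for v in x]
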