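"""Real-time performance metrics for target-acquisition trials.

Four session-level parameters: completion rate (CR, % of trials that reached
the target and completed the dwell within the 15 s limit), path efficiency
(PE, mean % ratio of net displacement to traveled path length), overshoot
(OS, target entries abandoned before dwell completion per 100 targets; can
exceed 100) and throughput (TP, mean index of difficulty over completion
time, bits/s, successful trials only — failed trials have no completion
time).  A Fitts'-law regression of mean completion time per index of
difficulty quantifies how well the trial set follows the speed–difficulty
law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class SessionMetrics:
    completion_rate: float  # %
    overshoot: float  # %
    path_efficiency: float  # %
    throughput: float  # bits/s
    n_trials: int
    n_success: int
    n_zero_travel: int  # trials excluded from PE because they never moved


def completion_rate(trials: Sequence) -> float:
    """Percentage of successfully completed trials."""
    if not trials:
        raise ValueError("no trials")
    return 100.0 * sum(t.success for t in trials) / len(trials)


def path_efficiency(trials: Sequence) -> float:
    """Mean of 100 * straight_line / traveled; zero-travel trials excluded.

    Returns NaN when every trial has zero travel.
    """
    if not trials:
        raise ValueError("no trials")
    ratios = [100.0 * t.straight_line / t.traveled for t in trials if t.traveled > 0]
    return float(np.mean(ratios)) if ratios else float("nan")


def overshoot(trials: Sequence) -> float:
    """Overshoot events per 100 targets (unbounded above)."""
    if not trials:
        raise ValueError("no trials")
    return 100.0 * sum(t.overshoot_events for t in trials) / len(trials)


def throughput(trials: Sequence) -> float:
    """Mean ID / completion-time over successful trials, bits/s."""
    if not trials:
        raise ValueError("no trials")
    values = [t.id_bits / t.completion_time for t in trials if t.success]
    return float(np.mean(values)) if values else float("nan")


def session_metrics(trials: Sequence) -> SessionMetrics:
    return SessionMetrics(
        completion_rate=completion_rate(trials),
        overshoot=overshoot(trials),
        path_efficiency=path_efficiency(trials),
        throughput=throughput(trials),
        n_trials=len(trials),
        n_success=sum(t.success for t in trials),
        n_zero_travel=sum(t.traveled == 0 for t in trials),
    )


def fitts_regression_xy(ids, completion_times) -> tuple[float, float, float]:
    """OLS of completion time on index of difficulty.

    Returns ``(slope, intercept, r_squared)``.  Inputs are typically the
    per-ID mean completion times (one point per difficulty level).
    """
    x = np.asarray(ids, dtype=float)
    y = np.asarray(completion_times, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (ID, CT) points")
    if np.ptp(x) == 0:
        raise ValueError("IDs are all identical; regression is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fitts_regression(trials: Sequence) -> tuple[float, float, float]:
    """Fitts regression on per-ID mean completion times of successful trials."""
    groups: dict[float, list[float]] = {}
    for t in trials:
        if t.success:
            groups.setdefault(round(t.id_bits, 2), []).append(t.completion_time)
    if len(groups) < 2:
        raise ValueError("need successful trials at >= 2 difficulty levels")
    ids = sorted(groups)
    means = [float(np.mean(groups[i])) for i in ids]
    return fitts_regression_xy(ids, means)
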