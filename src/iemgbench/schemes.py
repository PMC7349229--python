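"""Train/test schemes over the five-day design.

Real-time schemes (which calibration data trains the decoder tested on a
given day):

* WDT — within-day: train on the test day's own calibration data;
* BDT — between-day: train on the previous day's calibration data;
* CDT — combined-day: train on the pooled calibration data of all days up to
  and including the test day.

Offline counterparts (classification error on calibration feature windows):

* WCE — two-fold error within a day, folds split by repetition pairs
  ({1,2} vs {3,4}) so temporally adjacent windows never straddle folds;
* BCE — train previous day, test present day;
* CCE — train pooled former days, test present day.  ``include_present=True``
  additionally trains on the present day's first repetition pair and tests on
  the second, matching the real-time combined-day convention without
  train/test overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classifier import NetConfig, TrainedModel, classification_error, train
from .features import WindowingConfig, feature_matrix, feature_table
from .fitts_env import ControlConfig, run_session
from .metrics import SessionMetrics, session_metrics
from .synthetic_emg import SimConfig, SimulatedUser, generate_calibration_day, stream_rng

SCHEMES = ("WDT", "BDT", "CDT")
FOLD_REPETITIONS = ((1, 2), (3, 4))


@dataclass(frozen=True)
class SchemePlan:
    scheme: str
    test_day: int
    training_days: tuple[int, ...]


def build_plan(scheme: str, test_day: int) -> SchemePlan:
    """Training days for a scheme/test-day cell of the five-day design.

    BDT and CDT are undefined on day 1 (no previous day exists).
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not 1 <= test_day <= 5:
        raise ValueError("test_day must be in 1..5")
    if scheme == "WDT":
        days = (test_day,)
    elif scheme == "BDT":
        if test_day < 2:
            raise ValueError("BDT requires test_day >= 2")
        days = (test_day - 1,)
    else:  # CDT
        if test_day < 2:
            raise ValueError("CDT requires test_day >= 2")
        days = tuple(range(1, test_day + 1))
    return SchemePlan(scheme=scheme, test_day=test_day, training_days=days)


def all_plans(days: int = 5) -> list[SchemePlan]:
    """Every non-empty scheme/day cell of the design (13 for five days)."""
    plans = [build_plan("WDT", d) for d in range(1, days + 1)]
    plans += [build_plan("BDT", d) for d in range(2, days + 1)]
    plans += [build_plan("CDT", d) for d in range(2, days + 1)]
    return plans


# ---------------------------------------------------------------------------
# Offline classification errors
# ---------------------------------------------------------------------------


def _xy(table: pd.DataFrame, reps: tuple[int, ...] | None = None):
    if reps is not None:
        table = table[table["repetition"].isin(reps)]
    return feature_matrix(table)


def _fit(table: pd.DataFrame, cfg: NetConfig, classes, reps=None) -> TrainedModel:
    X, y = _xy(table, reps)
    return train(X, y, cfg, classes=classes)


def wce(
    day: int,
    features_by_day: Mapping[int, pd.DataFrame],
    cfg: NetConfig | None = None,
    classes=None,
) -> float:
    """Within-day two-fold classification error, percent.

    Folds are the repetition pairs {1,2} and {3,4}; the reported value is the
    mean of the two held-out fold errors.
    """
    cfg = cfg or NetConfig()
    table = features_by_day[day]
    errors = []
    for train_reps, test_reps in (FOLD_REPETITIONS, FOLD_REPETITIONS[::-1]):
        model = _fit(table, cfg, classes, reps=train_reps)
        X, y = _xy(table, test_reps)
        errors.append(classification_error(model, X, y))
    return 100.0 * float(np.mean(errors))


def bce(
    train_day: int,
    test_day: int,
    features_by_day: Mapping[int, pd.DataFrame],
    cfg: NetConfig | None = None,
    classes=None,
    model: TrainedModel | None = None,
) -> float:
    """Between-day classification error (train day i, test day j > i), percent."""
    if train_day >= test_day:
        raise ValueError("bce requires train_day < test_day")
    cfg = cfg or NetConfig()
    if model is None:
        model = _fit(features_by_day[train_day], cfg, classes)
    X, y = _xy(features_by_day[test_day])
    return 100.0 * classification_error(model, X, y)


def cce(
    test_day: int,
    features_by_day: Mapping[int, pd.DataFrame],
    cfg: NetConfig | None = None,
    classes=None,
    include_present: bool = False,
    model: TrainedModel | None = None,
) -> float:
    """Combined-day classification error, percent.

    Default trains on the pooled calibration data of all former days and
    tests on the whole present day.  ``include_present=True`` also pools the
    present day's first repetition pair into training and tests only on the
    second pair.  A pre-trained ``model`` (on the matching pooled training
    set) may be supplied to avoid re-fitting.
    """
    if test_day < 2:
        raise ValueError("cce requires test_day >= 2 (no former days otherwise)")
    cfg = cfg or NetConfig()
    if include_present:
        present = features_by_day[test_day]
        if model is None:
            former = pd.concat([features_by_day[d] for d in range(1, test_day)])
            train_table = pd.concat(
                [former, present[present["repetition"].isin(FOLD_REPETITIONS[0])]]
            )
            model = _fit(train_table, cfg, classes)
        X, y = _xy(present, FOLD_REPETITIONS[1])
    else:
        if model is None:
            former = pd.concat([features_by_day[d] for d in range(1, test_day)])
            model = _fit(former, cfg, classes)
        X, y = _xy(features_by_day[test_day])
    return 100.0 * classification_error(model, X, y)


# ---------------------------------------------------------------------------
# Real-time evaluation
# ---------------------------------------------------------------------------


@dataclass
class SchemeReport:
    """Aggregate of one scheme/day cell: per-session metrics and trials."""

    scheme: str
    day: int
    training_days: tuple[int, ...]
    sessions: dict[int, SessionMetrics]
    trials: pd.DataFrame  # one row per trial (no traces)
    model_meta: dict = field(default_factory=dict)


def _trials_frame(trials, scheme: str, day: int, session: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scheme": scheme,
            "day": day,
            "session": session,
            "trial": np.arange(len(trials)),
            "direction": [t.target.direction for t in trials],
            "distance": [t.target.distance for t in trials],
            "width": [t.target.width for t in trials],
            "id_bits": [t.id_bits for t in trials],
            "success": [t.success for t in trials],
            "completion_time": [t.completion_time for t in trials],
            "traveled": [t.traveled for t in trials],
            "straight_line": [t.straight_line for t in trials],
            "target_entries": [t.target_entries for t in trials],
            "overshoot_events": [t.overshoot_events for t in trials],
        }
    )


def train_plan_model(
    plan: SchemePlan,
    features_by_day: Mapping[int, pd.DataFrame],
    cfg: NetConfig | None = None,
    classes=None,
) -> TrainedModel:
    """Train the decoder for one plan on its pooled calibration features."""
    cfg = cfg or NetConfig()
    pooled = pd.concat([features_by_day[d] for d in plan.training_days])
    return _fit(pooled, cfg, classes)


def run_realtime_scheme(
    plan: SchemePlan,
    sim: SimConfig,
    sessions: int = 3,
    windowing: WindowingConfig | None = None,
    net: NetConfig | None = None,
    control: ControlConfig | None = None,
    seed: int = 0,
    features_by_day: Mapping[int, pd.DataFrame] | None = None,
    model: TrainedModel | None = None,
    decoder=None,
) -> SchemeReport:
    """Train one decoder per the plan and run Fitts sessions on the test day.

    ``features_by_day`` and ``model`` allow reuse of previously computed
    calibration features / trained decoders across schemes (the data are
    identical by construction thanks to deterministic seeding).  A
    ``decoder`` callable may be substituted for the trained model (e.g. an
    always-correct reference decoder), in which case no training happens.
    """
    windowing = windowing or WindowingConfig()
    net = net or NetConfig()
    control = control or ControlConfig()
    model_meta = {}
    if decoder is None:
        if features_by_day is None:
            features_by_day = {
                d: feature_table(generate_calibration_day(sim, d), windowing)
                for d in plan.training_days
            }
        if model is None:
            model = train_plan_model(plan, features_by_day, net, classes=sim.classes)
        decoder = model.as_decoder(windowing)
        model_meta = dict(model.meta)
    per_session: dict[int, SessionMetrics] = {}
    frames = []
    for s in range(1, sessions + 1):
        user = SimulatedUser(sim, day=plan.test_day, session=s)
        session_seed = int(
            stream_rng(seed, "session", plan.scheme, plan.test_day, s).integers(2**31)
        )
        trials = run_session(decoder, user, control, seed=session_seed)
        per_session[s] = session_metrics(trials)
        frames.append(_trials_frame(trials, plan.scheme, plan.test_day, s))
    return SchemeReport(
        scheme=plan.scheme,
        day=plan.test_day,
        training_days=plan.training_days,
        sessions=per_session,
        trials=pd.concat(frames, ignore_index=True),
        model_meta=model_meta,
    )
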