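"""Headless closed-loop virtual target-acquisition (Fitts'-law) environment.

Task rules: the cursor starts at the origin; a target of width W sits at
distance D along one of the four class axes (hand open = +Y, hand close = -Y,
wrist flexion = -X, wrist extension = +X).  A trial succeeds when the cursor
remains on the target for a continuous 1 s dwell; it fails if 15 s elapse
after the cue.  Each session presents the 24 unique targets (4 directions x
6 distance/width pairs) in seeded-random order, with the cursor re-centred
between trials.

Control law: bang-bang velocity.  Every 50 ms tick the simulated user emits
the latest 200 ms EMG window for its intended class — while outside the
target it steers, intending the motion whose direction most reduces the
remaining distance to the target centre (which also corrects off-axis
decoding errors and recovers from overshoots); while inside it intends rest
by default.  The decoder classifies the window and the cursor moves a fixed
``cursor_gain`` step along the decoded class axis (rest produces no motion).
The cursor trace is therefore a pure function of the decision sequence and
the control config.

Dwell restarts on target exit; the reported completion time includes the
final dwell second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .synthetic_emg import REST

# Axis convention: upward = hand open, downward = hand close, left = wrist
# flexion, right = wrist extension.  (The emulated protocol's two GUI
# descriptions disagree on the vertical mapping; this constant fixes one.)
DIRECTIONS: dict[str, np.ndarray] = {
    "hand_open": np.array([0.0, 1.0]),
    "hand_close": np.array([0.0, -1.0]),
    "wrist_flexion": np.array([-1.0, 0.0]),
    "wrist_extension": np.array([1.0, 0.0]),
}

#: The six distance/width combinations of the task (screen units).
D_W_PAIRS: tuple[tuple[float, float], ...] = (
    (50.0, 5.0),
    (50.0, 10.0),
    (50.0, 20.0),
    (100.0, 5.0),
    (100.0, 10.0),
    (100.0, 20.0),
)


def compute_id(distance: float, width: float) -> float:
    """Index of difficulty in bits: log2(D / W + 1)."""
    if distance <= 0 or width <= 0:
        raise ValueError("target distance and width must be positive")
    return float(np.log2(distance / width + 1.0))


@dataclass(frozen=True)
class TargetSpec:
    direction: str
    distance: float
    width: float

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.distance <= 0 or self.width <= 0:
            raise ValueError("distance and width must be positive")

    @property
    def id_bits(self) -> float:
        return compute_id(self.distance, self.width)

    @property
    def axis(self) -> np.ndarray:
        return DIRECTIONS[self.direction]

    def contains(self, pos: np.ndarray) -> bool:
        """Cursor-on-target test: within W/2 of the target centre along the
        movement axis and within W/2 of the axis transversally (with a tiny
        tolerance so accumulated float steps landing exactly on the edge
        count as inside)."""
        along = float(pos @ self.axis)
        off = float(pos @ np.array([-self.axis[1], self.axis[0]]))
        half = self.width / 2 + 1e-9
        return abs(along - self.distance) <= half and abs(off) <= half


def make_session_targets(seed: int) -> list[TargetSpec]:
    """The 24 unique session targets in seeded-random presentation order."""
    targets = [
        TargetSpec(direction, d, w)
        for direction in DIRECTIONS
        for (d, w) in D_W_PAIRS
    ]
    order = np.random.default_rng(seed).permutation(len(targets))
    return [targets[i] for i in order]


@dataclass
class ControlConfig:
    tick: float = 0.050
    window_len: float = 0.200
    cursor_gain: float = 0.8  # screen units per tick of active decision
    dwell_time: float = 1.0
    timeout: float = 15.0
    on_target_user_intent: str = "rest"  # or "continue"
    decision_smoothing: int = 3  # majority vote over the last m decisions

    def __post_init__(self):
        if self.tick <= 0 or self.cursor_gain <= 0:
            raise ValueError("tick and cursor_gain must be positive")
        if self.on_target_user_intent not in ("rest", "continue"):
            raise ValueError("on_target_user_intent must be 'rest' or 'continue'")
        if self.decision_smoothing < 1:
            raise ValueError("decision_smoothing must be >= 1")


@dataclass
class TrialResult:
    target: TargetSpec
    success: bool
    completion_time: float  # seconds from cue to dwell completion; NaN on failure
    traveled: float  # path length, screen units
    straight_line: float  # net start-to-end displacement, screen units
    target_entries: int
    overshoot_events: int
    trace: np.ndarray  # (n_ticks + 1, 2) cursor positions
    decisions: list = field(default_factory=list)

    @property
    def id_bits(self) -> float:
        return self.target.id_bits


class OracleDecoder:
    """Always-correct reference decoder: returns the user's intended class."""

    def __call__(self, window, intended):
        return intended


class ConstantDecoder:
    """Decoder that ignores its input and always emits one class."""

    def __init__(self, label: str = REST):
        self.label = label

    def __call__(self, window, intended):
        return self.label


def _smooth(decisions: list, m: int) -> str:
    """Majority vote over the last ``m`` raw decisions, most recent wins ties."""
    recent = decisions[-m:]
    if len(recent) == 1:
        return recent[0]
    counts: dict[str, int] = {}
    for d in recent:
        counts[d] = counts.get(d, 0) + 1
    best = max(counts.values())
    for d in reversed(recent):
        if counts[d] == best:
            return d


def replay_decisions(
    decisions: Sequence[str], cfg: ControlConfig, start: Sequence[float] = (0.0, 0.0)
) -> np.ndarray:
    """Reconstruct the cursor trace from a logged decision sequence.

    The cursor is a pure function of the decisions and the control config, so
    this reproduces a trial's trace bit-exactly.
    """
    pos = np.asarray(start, dtype=float).copy()
    trace = [pos.copy()]
    for d in decisions:
        if d != REST:
            pos = pos + cfg.cursor_gain * DIRECTIONS[d]
        trace.append(pos.copy())
    return np.array(trace)


def run_trial(
    decoder: Callable,
    user,
    target: TargetSpec,
    cfg: ControlConfig,
    seed: int | None = None,
) -> TrialResult:
    """Run one closed-loop target-acquisition attempt.

    ``decoder(window, intended) -> label`` maps the latest EMG window to a
    class (reference decoders may use ``intended``; model decoders ignore it).
    ``user`` follows the :class:`~iemgbench.synthetic_emg.SimulatedUser`
    protocol (``reset`` / ``emit``).
    """
    if seed is not None:
        user.reset(seed)
    known = set(DIRECTIONS) | {REST}
    max_ticks = int(round(cfg.timeout / cfg.tick))
    dwell_ticks = int(round(cfg.dwell_time / cfg.tick))
    gain = cfg.cursor_gain
    rest_on_target = cfg.on_target_user_intent == REST
    # scalar geometry (the loop is the hot path of every simulated session)
    ax, ay = float(target.axis[0]), float(target.axis[1])
    cx, cy = target.distance * ax, target.distance * ay
    half = target.width / 2.0
    steps = {c: (float(v[0]), float(v[1])) for c, v in DIRECTIONS.items()}
    px = py = 0.0
    trace = [(0.0, 0.0)]
    raw_decisions: list[str] = []
    decisions: list[str] = []
    traveled = 0.0
    entries = 0
    inside = False
    inside_count = 0
    success = False
    completion_time = float("nan")
    for k in range(1, max_ticks + 1):
        if inside and rest_on_target:
            intended = REST
        else:
            # closed-loop steering: the user intends the motion whose
            # direction most reduces the remaining distance to the target
            # centre (so off-axis decoding errors get corrected and an
            # overshot cursor is driven back, as a human subject would).
            # Tie-break follows the DIRECTIONS declaration order.
            dxe, dye = cx - px, cy - py
            best, intended = dye, "hand_open"
            if -dye > best:
                best, intended = -dye, "hand_close"
            if -dxe > best:
                best, intended = -dxe, "wrist_flexion"
            if dxe > best:
                best, intended = dxe, "wrist_extension"
        window = user.emit(intended, cfg.tick)
        raw = decoder(window, intended)
        if raw not in known:
            raise ValueError(f"decoder emitted unknown class {raw!r}")
        raw_decisions.append(raw)
        decided = _smooth(raw_decisions, cfg.decision_smoothing)
        decisions.append(decided)
        if decided != REST:
            sx, sy = steps[decided]
            px += gain * sx
            py += gain * sy
            traveled += gain
        trace.append((px, py))
        along = px * ax + py * ay
        off = -px * ay + py * ax
        # the 1e-9 slop admits float-accumulated positions on the exact edge
        now_inside = (
            abs(along - target.distance) <= half + 1e-9 and abs(off) <= half + 1e-9
        )
        if now_inside and not inside:
            entries += 1
            inside_count = 0
        if now_inside:
            inside_count += 1
            # inside_count tick-instants span (inside_count - 1) tick
            # intervals; the dwell completes after dwell_ticks full intervals.
            if inside_count >= dwell_ticks + 1:
                success = True
                completion_time = k * cfg.tick
                inside = True
                break
        inside = now_inside
    overshoot_events = entries - 1 if success else entries
    trace = np.array(trace)
    return TrialResult(
        target=target,
        success=success,
        completion_time=completion_time,
        traveled=traveled,
        straight_line=float(np.hypot(px, py)),
        target_entries=entries,
        overshoot_events=max(overshoot_events, 0),
        trace=trace,
        decisions=decisions,
    )


def run_session(
    decoder: Callable, user, cfg: ControlConfig, seed: int
) -> list[TrialResult]:
    """One test session: the 24 unique targets, fully reproducible from
    ``seed`` (target order and per-trial user noise streams)."""
    targets = make_session_targets(seed)
    trial_seeds = np.random.SeedSequence(seed).generate_state(len(targets))
    return [
        run_trial(decoder, user, target, cfg, seed=int(ts & 0x7FFFFFFF))
        for target, ts in zip(targets, trial_seeds)
    ]
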