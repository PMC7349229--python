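"""Target-acquisition environment: geometry, task rules, control loop."""

import math

import numpy as np
import pytest

from iemgbench import (
    ConstantDecoder,
    ControlConfig,
    OracleDecoder,
    SimulatedUser,
    TargetSpec,
    compute_id,
    make_session_targets,
    replay_decisions,
    run_session,
    run_trial,
)
from iemgbench.synthetic_emg import REST


class NullUser:
    """Silent EMG source for tests whose decoders ignore the signal."""

    def reset(self, seed):
        pass

    def emit(self, intended, advance):
        self.intended = intended
        return np.zeros((400, 3))


class ScriptedDecoder:
    """Plays back a fixed decision list, then rest forever."""

    def __init__(self, script):
        self.script = list(script)
        self.i = 0

    def __call__(self, window, intended):
        self.i += 1
        return self.script[self.i - 1] if self.i <= len(self.script) else REST


def oracle_completion_time(distance, width, cfg: ControlConfig) -> float:
    """Closed-form kinematics of a perfectly decoded straight approach:
    enter the target band after ceil((D - W/2)/gain) ticks, then hold for
    the full dwell."""
    k_enter = math.ceil((distance - width / 2) / cfg.cursor_gain)
    dwell_ticks = round(cfg.dwell_time / cfg.tick)
    return (k_enter + dwell_ticks) * cfg.tick


# ---------------------------------------------------------------------------
# Index of difficulty & targets
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d,w,expected",
    [(100, 5, 4.39), (50, 5, 3.46), (100, 10, 3.46), (50, 10, 2.59),
     (100, 20, 2.59), (50, 20, 1.81)],
)
def test_index_of_difficulty_values(d, w, expected):
    # printed-precision agreement; log2(6) = 2.58496 is printed as 2.59
    assert compute_id(d, w) == pytest.approx(expected, abs=0.0051)


def test_index_of_difficulty_identities():
    assert compute_id(10, 10) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_id(0, 5)
    with pytest.raises(ValueError):
        compute_id(5, -1)


def test_session_targets_are_24_unique_with_four_difficulty_levels():
    targets = make_session_targets(seed=0)
    assert len(targets) == 24
    assert len({(t.direction, t.distance, t.width) for t in targets}) == 24
    ids = sorted({round(t.id_bits, 3) for t in targets})
    assert ids == pytest.approx([1.81, 2.59, 3.46, 4.39], abs=0.0051)
    per_direction = {d: 0 for d in ("hand_open", "hand_close", "wrist_flexion", "wrist_extension")}
    for t in targets:
        per_direction[t.direction] += 1
    assert set(per_direction.values()) == {6}


def test_session_target_order_is_seeded_permutation():
    a, b = make_session_targets(1), make_session_targets(2)
    assert {(t.direction, t.distance, t.width) for t in a} == {
        (t.direction, t.distance, t.width) for t in b
    }
    assert [t.width for t in a] != [t.width for t in b]
    assert [t.width for t in make_session_targets(1)] == [t.width for t in a]


# ---------------------------------------------------------------------------
# Trial dynamics
# ---------------------------------------------------------------------------


def test_oracle_trial_matches_closed_form_kinematics():
    cfg = ControlConfig()
    for d, w in ((50.0, 5.0), (100.0, 20.0)):
        target = TargetSpec("wrist_extension", d, w)
        res = run_trial(OracleDecoder(), NullUser(), target, cfg, seed=0)
        assert res.success
        assert res.completion_time == pytest.approx(oracle_completion_time(d, w, cfg))
        k_enter = math.ceil((d - w / 2) / cfg.cursor_gain)
        # the majority vote adds (m-1)//2 lag steps after the intent flips
        moves = k_enter + (cfg.decision_smoothing - 1) // 2
        assert res.traveled == pytest.approx(moves * cfg.cursor_gain)
        assert res.overshoot_events == 0 and res.target_entries == 1
        assert res.straight_line == pytest.approx(res.traveled)  # monotone path


def test_always_rest_decoder_times_out():
    cfg = ControlConfig()
    res = run_trial(ConstantDecoder(REST), NullUser(), TargetSpec("hand_open", 50, 10), cfg)
    assert not res.success
    assert math.isnan(res.completion_time)
    assert res.traveled == 0.0
    assert len(res.decisions) == round(cfg.timeout / cfg.tick)


def test_unknown_decoder_class_is_an_error():
    cfg = ControlConfig()
    with pytest.raises(ValueError):
        run_trial(ConstantDecoder("grip"), NullUser(), TargetSpec("hand_open", 50, 10), cfg)


def test_dwell_resets_on_exit_and_overshoots_are_counted():
    """Enter, leave before the dwell completes, re-enter and finish: two
    entries, one overshoot event."""
    cfg = ControlConfig(cursor_gain=1.0, dwell_time=0.2, decision_smoothing=1)
    target = TargetSpec("hand_open", 4.0, 2.0)  # band [3, 5]
    up, down = "hand_open", "hand_close"
    script = [up] * 4          # enters the band [3, 5] at tick 3
    script += [up, up]         # tick 6 reaches y=6: exit before the dwell
    script += [down, down]     # tick 7 re-enters at y=5
    res = run_trial(ScriptedDecoder(script), NullUser(), target, cfg)
    assert res.success
    assert res.target_entries == 2
    assert res.overshoot_events == 1
    # re-entry at tick 7, dwell = 4 further tick intervals -> tick 11
    assert res.completion_time == pytest.approx(11 * cfg.tick)


def test_failure_counts_all_entries_as_overshoots():
    cfg = ControlConfig(cursor_gain=1.0, dwell_time=1.0, timeout=1.0)
    target = TargetSpec("hand_open", 3.0, 2.0)
    script = ["hand_open"] * 3 + ["hand_open"] * 3  # pass straight through
    res = run_trial(ScriptedDecoder(script), NullUser(), target, cfg)
    assert not res.success
    assert res.target_entries == 1
    assert res.overshoot_events == 1


def test_trace_is_replayable_from_decisions():
    cfg = ControlConfig(cursor_gain=1.0, dwell_time=0.2)
    script = ["hand_open", "wrist_flexion", REST, "hand_open", "hand_close"]
    res = run_trial(ScriptedDecoder(script + ["hand_open"] * 40), NullUser(),
                    TargetSpec("hand_open", 30.0, 4.0), cfg)
    assert np.array_equal(replay_decisions(res.decisions, cfg), res.trace)


def test_decision_smoothing_majority_vote():
    """With a 3-vote majority, isolated decoder flickers do not move the
    cursor in the flicker direction."""
    cfg = ControlConfig(cursor_gain=1.0, dwell_time=0.2, decision_smoothing=3,
                        timeout=0.5)
    script = ["hand_open", "hand_open", "hand_close", "hand_open", "hand_open"]
    res = run_trial(ScriptedDecoder(script), NullUser(),
                    TargetSpec("hand_open", 100.0, 4.0), cfg)
    # the single flicker is outvoted; one lagging vote after the script ends
    assert res.decisions == ["hand_open"] * 6 + [REST] * 4


def test_steering_recovers_from_overshoot():
    """After overshooting past the target, the user's intent reverses."""
    cfg = ControlConfig(cursor_gain=1.0, dwell_time=0.2, decision_smoothing=1)
    target = TargetSpec("hand_open", 4.0, 2.0)
    user = NullUser()
    script = [target.direction] * 8  # drive to y=8, far beyond the band [3,5]
    run_trial(ScriptedDecoder(script + [REST]), user, target, cfg)
    assert user.intended == "hand_close"  # steering now points back down


def test_noisy_decoder_degrades_control_quality():
    """A decoder with 20% symmetric confusion moves the cursor off the ideal
    path: PE < 100%, overshoots appear, completion takes longer than the
    oracle, and CR cannot exceed the oracle's (steering and the generous
    15 s budget still recover most trials at this error rate)."""
    from iemgbench import completion_rate, overshoot, path_efficiency

    sim_rng = np.random.default_rng(99)
    classes = ("hand_open", "hand_close", "wrist_flexion", "wrist_extension", REST)

    def noisy(window, intended):
        if sim_rng.random() < 0.2:
            return classes[sim_rng.integers(len(classes))]
        return intended

    # raw decisions (no majority vote) so the confusion rate acts per tick
    cfg = ControlConfig(decision_smoothing=1)
    target = TargetSpec("wrist_flexion", 50.0, 5.0)
    trials = [run_trial(noisy, NullUser(), target, cfg) for _ in range(50)]
    oracle = [run_trial(OracleDecoder(), NullUser(), target, cfg) for _ in range(2)]
    assert path_efficiency(trials) < 95.0
    assert overshoot(trials) > overshoot(oracle)
    assert completion_rate(trials) <= completion_rate(oracle)
    mean_ct = np.nanmean([t.completion_time for t in trials])
    assert mean_ct > oracle[0].completion_time


def test_oracle_completion_time_nondecreasing_in_difficulty():
    """Fitts-consistency by construction: per-ID mean oracle completion time
    increases with the index of difficulty."""
    cfg = ControlConfig()
    by_id = {}
    for t in make_session_targets(0):
        by_id.setdefault(round(t.id_bits, 2), []).append(
            oracle_completion_time(t.distance, t.width, cfg)
        )
    ids = sorted(by_id)
    means = [np.mean(by_id[i]) for i in ids]
    assert all(b >= a for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------


def test_session_runs_24_trials_all_from_origin(sim_nodrift):
    user = SimulatedUser(sim_nodrift, day=1, session=1)
    trials = run_session(OracleDecoder(), user, ControlConfig(), seed=5)
    assert len(trials) == 24
    assert all(t.success for t in trials)
    assert all(np.array_equal(t.trace[0], [0.0, 0.0]) for t in trials)


def test_session_is_reproducible(sim_default):
    cfg = ControlConfig()
    user = SimulatedUser(sim_default, day=2, session=1)
    a = run_session(OracleDecoder(), user, cfg, seed=9)
    b = run_session(OracleDecoder(), user, cfg, seed=9)
    assert [t.completion_time for t in a] == [t.completion_time for t in b]
    assert all(np.array_equal(x.trace, y.trace) for x, y in zip(a, b))


def test_control_config_validation():
    with pytest.raises(ValueError):
        ControlConfig(cursor_gain=0.0)
    with pytest.raises(ValueError):
        ControlConfig(on_target_user_intent="hold")
    with pytest.raises(ValueError):
        ControlConfig(decision_smoothing=0)
    with pytest.raises(ValueError):
        TargetSpec("sideways", 50, 5)
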