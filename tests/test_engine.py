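"""Trial engine: schedules, the mat-gated state machine, sessions, CSV I/O."""

import dataclasses
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psychopig.engine import (
    ConfigError,
    DataError,
    SessionConfig,
    TrialEngine,
    make_schedule,
    read_session_csv,
    run_session,
    run_sessions,
    write_session_csv,
)
from psychopig.observer import ObserverParams, preset
from psychopig.stimuli import STANDARD_CONTRASTS


def training_config(**kw):
    base = dict(phase="self_run_training", contrast_levels=[1.0],
                reps_per_contrast=50, max_trials=50, seed=0)
    base.update(kw)
    return SessionConfig(**base)


# --- configuration ----------------------------------------------------------

def test_experiment_phase_requires_standard_contrast_set():
    with pytest.raises(ConfigError):
        SessionConfig(phase="experiment", contrast_levels=[0.5, 1.0])


def test_self_run_training_requires_full_contrast_only():
    with pytest.raises(ConfigError):
        SessionConfig(phase="self_run_training", contrast_levels=[0.5])


def test_unusual_session_size_is_flagged_not_rejected():
    with pytest.warns(UserWarning, match="50-100"):
        SessionConfig(phase="self_run_training", contrast_levels=[1.0],
                      reps_per_contrast=200, max_trials=200)


def test_empty_contrast_list_rejected():
    with pytest.raises(ConfigError):
        SessionConfig(phase="operator_training", contrast_levels=[])


# --- schedules --------------------------------------------------------------

def test_experiment_schedule_composition():
    """10 levels x 10 reps: 100 trials, each contrast exactly 10 times."""
    sched = make_schedule(SessionConfig(seed=4))
    assert len(sched) == 100
    counts = Counter(t.contrast for t in sched)
    assert all(counts[c] == 10 for c in STANDARD_CONTRASTS)


def test_sides_counterbalanced_within_contrast():
    sched = make_schedule(SessionConfig(seed=9))
    by_contrast = {}
    for t in sched:
        by_contrast.setdefault(t.contrast, []).append(t.target_side)
    for sides in by_contrast.values():
        assert Counter(sides) == {1: 5, 2: 5}


def test_single_level_schedule_counterbalanced():
    sched = make_schedule(training_config(seed=2))
    sides = Counter(t.target_side for t in sched)
    assert sides == {1: 25, 2: 25}


def test_schedule_deterministic_per_seed():
    cfg = SessionConfig(seed=123)
    assert make_schedule(cfg) == make_schedule(cfg)
    other = make_schedule(SessionConfig(seed=124))
    assert make_schedule(cfg) != other


def test_schedule_truncates_to_max_trials():
    cfg = SessionConfig(seed=0, max_trials=60)
    assert len(make_schedule(cfg)) == 60


def test_iid_sides_flag_breaks_counterbalance_guarantee():
    cfg = SessionConfig(seed=1, iid_sides=True)
    sched = make_schedule(cfg)
    assert len(sched) == 100
    # still a valid two-panel assignment, just not exactly balanced
    assert {t.target_side for t in sched} <= {1, 2}


@settings(deadline=None, max_examples=40)
@given(seed=st.integers(0, 2**31 - 1))
def test_schedule_invariants_hold_for_every_seed(seed):
    sched = make_schedule(SessionConfig(seed=seed))
    counts = Counter(t.contrast for t in sched)
    assert all(counts[c] == 10 for c in STANDARD_CONTRASTS)
    assert [t.trial_index for t in sched] == list(range(1, 101))


# --- trial lifecycle --------------------------------------------------------

def test_reward_contingency():
    engine = TrialEngine(SessionConfig(seed=0))
    engine.mat_step_on()
    target = engine.current_trial().target_side
    rec = engine.touch(target, latency_s=2.0)
    assert rec.correct and rec.rewarded
    engine.mat_step_off(); engine.mat_step_on()
    wrong = 3 - engine.current_trial().target_side
    rec = engine.touch(wrong, latency_s=2.0)
    assert rec.correct is False and not rec.rewarded


def test_touch_before_arming_is_ignored():
    engine = TrialEngine(SessionConfig(seed=0))
    assert engine.touch(1, latency_s=1.0) is None  # never armed
    engine.mat_step_on()
    assert engine.touch(1, latency_s=1.0) is not None
    # no off/on cycle since the trial: next touch must be ignored
    assert engine.touch(1, latency_s=1.0) is None
    engine.mat_step_on()  # still standing on the mat: does not re-arm
    assert engine.touch(1, latency_s=1.0) is None
    engine.mat_step_off(); engine.mat_step_on()
    assert engine.touch(2, latency_s=1.0) is not None


def test_subthreshold_touch_area_is_ignored():
    engine = TrialEngine(SessionConfig(seed=0))
    engine.mat_step_on()
    assert engine.touch(1, latency_s=1.0, valid=False) is None
    assert engine.armed  # trial still pending


def test_timeout_records_aborted_trial():
    cfg = SessionConfig(seed=0, response_timeout_s=30.0)
    engine = TrialEngine(cfg)
    engine.mat_step_on()
    rec = engine.touch(1, latency_s=31.0)
    assert rec.aborted and rec.chosen_side is None and rec.correct is None
    assert not rec.rewarded and rec.latency_s is None


# --- sessions ---------------------------------------------------------------

def test_fatigue_truncates_session(good_cs_observer):
    tired = dataclasses.replace(good_cs_observer, fatigue_trials=60)
    log = run_session(SessionConfig(seed=5), tired)
    assert len(log.trials) == 60
    assert all(not t.aborted for t in log.trials)


def test_perfect_observer_scores_100_percent():
    log = run_session(SessionConfig(seed=8), preset("perfect"))
    assert len(log.trials) == 100
    assert all(t.correct for t in log.trials)
    assert log.n_rewards == 100


def test_rewards_equal_correct_trials(good_cs_logs):
    for log in good_cs_logs:
        assert log.n_rewards == sum(1 for t in log.trials if t.correct)


def test_session_reproducible_from_seeds(good_cs_observer):
    cfg = SessionConfig(seed=42)
    a = run_session(cfg, good_cs_observer)
    b = run_session(cfg, good_cs_observer)
    assert a.trials == b.trials


def test_observer_seed_changes_outcomes_not_schedule(good_cs_observer):
    cfg = SessionConfig(seed=42)
    a = run_session(cfg, good_cs_observer)
    b = run_session(cfg, dataclasses.replace(good_cs_observer, seed=99))
    assert [(t.contrast, t.target_side) for t in a.trials] == \
           [(t.contrast, t.target_side) for t in b.trials]
    assert a.trials != b.trials


def test_run_sessions_advances_dates_and_learning():
    learner = preset("learner")
    logs = run_sessions(SessionConfig(seed=3), learner, 3)
    assert [log.session_date for log in logs] == \
           ["2026-01-01", "2026-01-02", "2026-01-03"]
    assert len({log.session_date for log in logs}) == 3


# --- CSV dialect ------------------------------------------------------------

def test_session_csv_round_trip(tmp_path, good_cs_logs):
    log = good_cs_logs[0]
    path = write_session_csv(log, tmp_path / "s1.csv")
    back = read_session_csv(path)
    assert back.animal_id == log.animal_id
    assert back.session_date == log.session_date
    assert back.trials == log.trials


def test_csv_aborted_fields_empty(tmp_path, good_cs_observer):
    cfg = SessionConfig(seed=1, response_timeout_s=0.001)
    log = run_session(cfg, good_cs_observer)
    assert all(t.aborted for t in log.trials)
    path = write_session_csv(log, tmp_path / "ab.csv")
    text = path.read_text().splitlines()
    assert text[1].split(",")[6] == ""  # chosen_side empty
    back = read_session_csv(path)
    assert back.trials == log.trials


def test_csv_missing_columns_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("animal_id,contrast\na,0.5\n")
    with pytest.raises(DataError):
        read_session_csv(p)


def test_csv_empty_log_rejected(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text(
        "animal_id,session_date,phase,trial_index,contrast,target_side,"
        "chosen_side,correct,latency_s,rewarded,aborted\n"
    )
    with pytest.raises(DataError):
        read_session_csv(p)
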