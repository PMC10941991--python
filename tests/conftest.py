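from __future__ import annotations

import pytest

from psychopig import (
    ObserverParams,
    SessionConfig,
    SessionLog,
    TrialRecord,
    preset,
    run_sessions,
)


@pytest.fixture(scope="session")
def good_cs_observer() -> ObserverParams:
    return preset("good_cs")


@pytest.fixture(scope="session")
def experiment_config() -> SessionConfig:
    return SessionConfig(seed=7)


@pytest.fixture(scope="session")
def good_cs_logs(experiment_config, good_cs_observer):
    """Four experimental sessions of the good-CS observer, reused widely."""
    return run_sessions(experiment_config, good_cs_observer, 4)


def make_log(trials, animal_id="t", session_date="2026-01-01", phase="operator_training"):
    """Build a SessionLog from (contrast, target, chosen, latency) tuples.

    ``chosen=None`` marks an aborted trial.  The operator_training
    phase places no constraint on the contrast set, so arbitrary
    hand-written trials are accepted.
    """
    contrasts = sorted({c for c, *_ in trials}) or [1.0]
    config = SessionConfig(
        phase=phase,
        contrast_levels=contrasts,
        reps_per_contrast=max(1, len(trials)),
        max_trials=max(50, len(trials)),
    )
    records = []
    for i, (contrast, target, chosen, latency) in enumerate(trials, start=1):
        aborted = chosen is None
        correct = None if aborted else chosen == target
        records.append(TrialRecord(
            trial_index=i,
            contrast=contrast,
            target_side=target,
            chosen_side=chosen,
            correct=correct,
            latency_s=None if aborted else latency,
            rewarded=bool(correct),
            aborted=aborted,
        ))
    return SessionLog(animal_id=animal_id, session_date=session_date,
                      config=config, trials=records)
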