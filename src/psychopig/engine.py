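"""Self-run trial protocol as a deterministic-given-seed state machine.

A session is a sequence of two-choice trials.  The screen is split by a
mask into two equal panels (side 1 = left, side 2 = right); each trial
shows the striped target on one panel and the gray control on the
other.  A weight-sensitive mat in front of the screen gates trial
onset: the screen only activates after the animal has stepped OFF the
mat (to collect a pellet) and back ON, guaranteeing it faces the screen
when the stimulus appears — which is what makes the activation-to-touch
latency meaningful.  A correct touch dispenses one pellet; a touch on
the control panel ends the trial without reward.

The mat is modeled as an arm/disarm token in the event stream, and the
touchscreen's 1 cm^2 minimum contact area as a validity flag on touch
events; invalid touches and touches before arming are ignored.

Randomness is split into two named sub-streams derived from separate
seeds — the schedule stream (trial order and target sides) and the
observer stream (choices and latencies) — so either can be held fixed.
Identical seed pairs reproduce bit-identical session logs.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .observer import ObserverParams, advance_session, respond
from .stimuli import STANDARD_CONTRASTS

__all__ = [
    "SessionConfig",
    "ScheduledTrial",
    "TrialSchedule",
    "TrialRecord",
    "SessionLog",
    "TrialEngine",
    "make_schedule",
    "run_session",
    "run_sessions",
    "write_session_csv",
    "read_session_csv",
]

logger = logging.getLogger(__name__)

PHASES = ("operator_training", "self_run_training", "experiment")

# Sub-stream tags keeping schedule and observer randomness independent.
_SCHEDULE_STREAM = 0
_OBSERVER_STREAM = 1


class ConfigError(ValueError):
    """Invalid session configuration."""


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one training or experimental session.

    Phase constraints mirror the protocol: self-run training uses only
    the 100%-contrast target; the experimental phase uses the standard
    10-level contrast set presented ``reps_per_contrast`` times each
    (10 by default, giving the canonical 100-trial session).  Sessions
    outside the usual 50-100 trial range are allowed but flagged with a
    warning, since animals complete 50-100 consecutive trials before
    fatigue.
    """

    phase: str = "experiment"
    contrast_levels: Sequence[float] = STANDARD_CONTRASTS
    reps_per_contrast: int = 10
    max_trials: int = 100
    seed: int = 0
    mean_luminance: float = 127.5
    spatial_frequency: int = 8
    response_timeout_s: Optional[float] = None
    iid_sides: bool = False

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ConfigError(f"phase must be one of {PHASES}, got {self.phase!r}")
        levels = tuple(float(c) for c in self.contrast_levels)
        object.__setattr__(self, "contrast_levels", levels)
        if not levels:
            raise ConfigError("contrast_levels must be non-empty")
        if any(not 0.0 <= c <= 1.0 for c in levels):
            raise ConfigError("contrast levels must lie in [0, 1]")
        if self.phase == "self_run_training" and levels != (1.0,):
            raise ConfigError("self_run_training uses only the 100% contrast image")
        if self.phase == "experiment" and levels != tuple(STANDARD_CONTRASTS):
            raise ConfigError(
                "experiment phase uses the standard 10-level contrast set"
            )
        if self.reps_per_contrast < 1 or self.max_trials < 1:
            raise ConfigError("reps_per_contrast and max_trials must be positive")
        if not 50 <= self.max_trials <= 100:
            warnings.warn(
                f"max_trials={self.max_trials} outside the usual 50-100 range",
                stacklevel=3,
            )
        if self.response_timeout_s is not None and self.response_timeout_s <= 0:
            raise ConfigError("response_timeout_s must be positive or None")


@dataclass(frozen=True)
class ScheduledTrial:
    trial_index: int  # 1-based
    contrast: float
    target_side: int  # 1 or 2


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[ScheduledTrial, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial; aborted trials carry no choice or latency."""

    trial_index: int
    contrast: float
    target_side: int
    chosen_side: Optional[int]
    correct: Optional[bool]
    latency_s: Optional[float]
    rewarded: bool
    aborted: bool
    operator_guided: bool = False

    def __post_init__(self) -> None:
        if self.aborted:
            if self.chosen_side is not None or self.correct is not None:
                raise ValueError("aborted trials have no choice or outcome")
        if self.rewarded != (self.correct is True):
            raise ValueError("reward contingency violated: rewarded <=> correct")
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError("latency must be nonnegative")


@dataclass
class SessionLog:
    animal_id: str
    session_date: str  # ISO-8601
    config: SessionConfig
    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return sum(1 for t in self.trials if not t.aborted)

    @property
    def n_rewards(self) -> int:
        return sum(1 for t in self.trials if t.rewarded)


def make_schedule(config: SessionConfig) -> TrialSchedule:
    """Build the seeded trial schedule.

    Each contrast appears ``reps_per_contrast`` times.  Target sides
    are counterbalanced within each contrast (reps split as evenly as
    possible between panels, an odd remainder assigned at random) and
    the whole list is then shuffled; ``iid_sides=True`` instead draws
    each side as an independent fair coin, matching a literal "randomly
    presented on one side".  The schedule is truncated to
    ``max_trials`` if necessary.
    """
    rng = np.random.default_rng([_SCHEDULE_STREAM, config.seed])
    pairs: list[tuple[float, int]] = []
    for c in config.contrast_levels:
        reps = config.reps_per_contrast
        if config.iid_sides:
            sides = list(rng.integers(1, 3, size=reps))
        else:
            sides = [1] * (reps // 2) + [2] * (reps // 2)
            if reps % 2:
                sides.append(int(rng.integers(1, 3)))
        pairs.extend((c, int(s)) for s in sides)
    order = rng.permutation(len(pairs))
    n = min(config.max_trials, len(pairs))
    trials = tuple(
        ScheduledTrial(trial_index=i + 1, contrast=pairs[j][0], target_side=pairs[j][1])
        for i, j in enumerate(order[:n])
    )
    return TrialSchedule(trials=trials)


class TrialEngine:
    """Event-driven trial lifecycle: mat arm -> display -> touch -> re-arm.

    The engine begins with the mat unoccupied; the first ``mat_step_on``
    arms the first trial.  After each completed trial the engine
    disarms and requires a full mat cycle (step off, then step on)
    before the next stimulus is displayed.
    """

    def __init__(self, config: SessionConfig, schedule: TrialSchedule | None = None):
        self.config = config
        self.schedule = schedule if schedule is not None else make_schedule(config)
        self._next = 0  # index into schedule
        self._armed = False
        self._mat_occupied = False

    @property
    def armed(self) -> bool:
        return self._armed

    @property
    def finished(self) -> bool:
        return self._next >= len(self.schedule)

    def current_trial(self) -> ScheduledTrial:
        if self.finished:
            raise IndexError("schedule exhausted")
        return self.schedule[self._next]

    def mat_step_on(self) -> bool:
        """Animal steps on the mat; arms the next trial if not finished."""
        if self._mat_occupied:
            return self._armed  # no off->on cycle, nothing changes
        self._mat_occupied = True
        if not self._armed and not self.finished:
            self._armed = True
            logger.debug("trial %d armed", self.current_trial().trial_index)
        return self._armed

    def mat_step_off(self) -> None:
        self._mat_occupied = False

    def touch(self, side: Optional[int], latency_s: float, valid: bool = True
              ) -> Optional[TrialRecord]:
        """Process a touch event; returns a record or None if ignored.

        Touches before arming or below the minimum contact area
        (``valid=False``) are ignored.  When a response timeout is
        configured and the touch arrives after it, the trial is
        recorded as aborted (no choice, no reward).
        """
        if not self._armed or not valid:
            return None
        sched = self.current_trial()
        timeout = self.config.response_timeout_s
        if side is None or (timeout is not None and latency_s > timeout):
            rec = TrialRecord(
                trial_index=sched.trial_index,
                contrast=sched.contrast,
                target_side=sched.target_side,
                chosen_side=None,
                correct=None,
                latency_s=None,
                rewarded=False,
                aborted=True,
            )
        else:
            if side not in (1, 2):
                raise ValueError(f"touch side must be 1 or 2, got {side}")
            correct = side == sched.target_side
            rec = TrialRecord(
                trial_index=sched.trial_index,
                contrast=sched.contrast,
                target_side=sched.target_side,
                chosen_side=side,
                correct=correct,
                latency_s=latency_s,
                rewarded=correct,  # pellet iff the target panel was touched
                aborted=False,
            )
        self._next += 1
        self._armed = False
        logger.debug(
            "trial %d: contrast=%.2f target=%d chosen=%s correct=%s",
            rec.trial_index, rec.contrast, rec.target_side,
            rec.chosen_side, rec.correct,
        )
        return rec


def run_session(
    config: SessionConfig,
    observer: ObserverParams,
    animal_id: str = "sim",
    session_date: str = "2026-01-01",
) -> SessionLog:
    """Simulate one full session of an observer on the protocol.

    The session iterates the seeded schedule, arming each trial with a
    mat cycle and querying the observer for a touch, and stops at the
    schedule's end or the observer's fatigue point, whichever comes
    first.  Fully reproducible from ``(config.seed, observer.seed)``.
    """
    engine = TrialEngine(config)
    rng = np.random.default_rng([_OBSERVER_STREAM, observer.seed])
    log = SessionLog(animal_id=animal_id, session_date=session_date, config=config)
    engine.mat_step_on()
    while not engine.finished:
        if (
            observer.fatigue_trials is not None
            and len(log.trials) >= observer.fatigue_trials
        ):
            logger.info("%s: fatigue after %d trials", animal_id, len(log.trials))
            break
        sched = engine.current_trial()
        side, latency = respond(observer, sched.contrast, sched.target_side, rng)
        rec = engine.touch(side, latency)
        assert rec is not None
        log.trials.append(rec)
        engine.mat_step_off()  # walks to the pellet dispenser ...
        engine.mat_step_on()   # ... and back over the mat
    logger.info(
        "%s %s: %d trials, %d rewards",
        animal_id, session_date, len(log.trials), log.n_rewards,
    )
    return log


def run_sessions(
    config: SessionConfig,
    observer: ObserverParams,
    n_sessions: int,
    animal_id: str = "sim",
    start_date: str = "2026-01-01",
) -> list[SessionLog]:
    """Simulate consecutive sessions with per-session learning.

    Session ``i`` uses schedule seed ``config.seed + i`` and observer
    seed ``observer.seed + i``, and the observer's slope grows by its
    learning rate between sessions.
    """
    import datetime as _dt

    d0 = _dt.date.fromisoformat(start_date)
    logs = []
    params = observer
    for i in range(n_sessions):
        cfg = replace(config, seed=config.seed + i)
        obs = replace(params, seed=observer.seed + i)
        logs.append(
            run_session(cfg, obs, animal_id=animal_id,
                        session_date=(d0 + _dt.timedelta(days=i)).isoformat())
        )
        params = advance_session(params)
    return logs


# --- SessionLog CSV dialect -------------------------------------------------
#
# One row per trial, header mandatory, UTF-8, '.' decimal, ISO-8601 dates;
# booleans are written as 'true'/'false'; fields that are logically 'none'
# (choice/outcome/latency of aborted trials) are left empty.

CSV_COLUMNS = (
    "animal_id", "session_date", "phase", "trial_index", "contrast",
    "target_side", "chosen_side", "correct", "latency_s", "rewarded", "aborted",
)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_session_csv(log: SessionLog, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for t in log.trials:
            w.writerow([
                _fmt(log.animal_id), _fmt(log.session_date), _fmt(log.config.phase),
                _fmt(t.trial_index), _fmt(t.contrast), _fmt(t.target_side),
                _fmt(t.chosen_side), _fmt(t.correct), _fmt(t.latency_s),
                _fmt(t.rewarded), _fmt(t.aborted),
            ])
    return path


class DataError(ValueError):
    """Malformed session-log data."""


def _parse_bool(s: str) -> Optional[bool]:
    if s == "":
        return None
    if s.lower() in ("true", "1"):
        return True
    if s.lower() in ("false", "0"):
        return False
    raise DataError(f"bad boolean {s!r}")


def read_session_csv(path: str | Path) -> SessionLog:
    """Read one session log in the trial CSV dialect.

    Logs converted from real touchscreen systems only need the listed
    columns; the attached :class:`SessionConfig` is reconstructed
    minimally (phase and the observed contrast levels).
    """
    path = Path(path)
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(CSV_COLUMNS) <= set(reader.fieldnames):
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: no trials")
    phase = rows[0]["phase"]
    animal_id = rows[0]["animal_id"]
    session_date = rows[0]["session_date"]
    contrasts = sorted({float(r["contrast"]) for r in rows})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # foreign logs may have odd trial counts
        try:
            config = SessionConfig(
                phase=phase,
                contrast_levels=contrasts,
                reps_per_contrast=max(1, len(rows) // max(1, len(contrasts))),
                max_trials=max(len(rows), 1),
            )
        except ConfigError:
            # foreign log whose contrast set does not match a phase template
            config = SessionConfig(
                phase="operator_training",
                contrast_levels=contrasts,
                reps_per_contrast=1,
                max_trials=max(len(rows), 1),
            )
    trials = []
    for row in rows:
        try:
            trials.append(TrialRecord(
                trial_index=int(row["trial_index"]),
                contrast=float(row["contrast"]),
                target_side=int(row["target_side"]),
                chosen_side=int(row["chosen_side"]) if row["chosen_side"] else None,
                correct=_parse_bool(row["correct"]),
                latency_s=float(row["latency_s"]) if row["latency_s"] else None,
                rewarded=_parse_bool(row["rewarded"]) or False,
                aborted=_parse_bool(row["aborted"]) or False,
                operator_guided=phase == "operator_training",
            ))
        except (ValueError, KeyError) as exc:
            raise DataError(f"{path}: bad trial row {row}: {exc}") from exc
    return SessionLog(
        animal_id=animal_id, session_date=session_date, config=config, trials=trials
    )


def read_session_logs(paths: Iterable[str | Path]) -> list[SessionLog]:
    return [read_session_csv(p) for p in sorted(Path(p) for p in paths)]
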