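"""Task vocabulary, outcome rules, SSD staircase and session design.

The task: on every trial the participant reacts to a Go signal by moving two
effectors at once (a wrist extension and a foot flexion).  On a minority of
trials a Stop signal appears after an adaptively tracked delay (the Stop
Signal Delay, SSD) and requires cancelling both movements (non-selective
``stop_both``) or exactly one of them (selective ``stop_wrist`` /
``stop_foot``).  Sessions come in two contexts: *block* sessions present a
single stop version throughout (the effector to stop is known in advance),
*mix* sessions interleave all three versions so the effector to stop is only
revealed by the Stop signal itself.

This module holds the shared vocabulary (effectors, stop versions, trial
records), the trial-outcome classification rules, the one-up/one-down SSD
staircase that tracks ~50% stopping success, and the exact-count trial
allocation used both by the generative simulator and when analysing recorded
trial tables.

Conventions: all times are real-valued milliseconds measured from Go-signal
onset (t = 0); the Stop signal occurs at t = SSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Invalid session or model configuration."""


class MalformedTrialError(ValueError):
    """A trial row violates the record invariants (e.g. moved without RT)."""


class InvalidStateError(ValueError):
    """A staircase or estimator reached a non-finite / impossible state."""


class Effector(str, Enum):
    WRIST = "wrist"
    FOOT = "foot"


class StopVersion(str, Enum):
    STOP_BOTH = "stop_both"
    STOP_WRIST = "stop_wrist"
    STOP_FOOT = "stop_foot"

    @property
    def is_selective(self) -> bool:
        return self is not StopVersion.STOP_BOTH

    @property
    def stopped_effector(self) -> Optional[Effector]:
        """The effector that must be cancelled (None for stop_both: both)."""
        if self is StopVersion.STOP_WRIST:
            return Effector.WRIST
        if self is StopVersion.STOP_FOOT:
            return Effector.FOOT
        return None

    @property
    def moving_effector(self) -> Optional[Effector]:
        """The effector that must keep moving (selective versions only)."""
        if self is StopVersion.STOP_WRIST:
            return Effector.FOOT
        if self is StopVersion.STOP_FOOT:
            return Effector.WRIST
        return None


class TaskCondition(str, Enum):
    BLOCK = "block"
    MIX = "mix"


class TrialOutcome(str, Enum):
    CORRECT = "correct"
    ERROR = "error"
    ABORTED = "aborted"


NO_STOP = "no_stop"
STOP = "stop"


@dataclass
class TrialRecord:
    """One trial of a session, as stored in delimited trial tables.

    ``mus_rt`` is the muscle reaction time (Go signal to EMG burst onset),
    ``rt`` the overt movement time (Go signal to switch release); for a moved
    effector ``mus_rt <= rt`` because the electromechanical delay is
    non-negative.
    """

    trial_index: int
    trial_type: str  # NO_STOP | STOP
    participant_id: str = "p0"
    condition: TaskCondition = TaskCondition.BLOCK
    stop_version: Optional[StopVersion] = None
    ssd: Optional[float] = None
    wrist_moved: bool = False
    foot_moved: bool = False
    wrist_mus_rt: Optional[float] = None
    foot_mus_rt: Optional[float] = None
    wrist_rt: Optional[float] = None
    foot_rt: Optional[float] = None
    outcome: Optional[TrialOutcome] = None


@dataclass(frozen=True)
class SessionConfig:
    """Design parameters of one session.

    Defaults follow the standard design: 30% stop trials, 1300 ms upper RT
    limit, at most 200 ms between the two effectors' movements, a 1300 ms
    hold after a non-selective Stop signal, and an SSD staircase starting at
    50 ms with 50 ms steps.  ``block_version`` selects the single stop
    version of a block session and must be set when ``condition`` is block.
    """

    n_trials: int = 300
    condition: TaskCondition = TaskCondition.BLOCK
    block_version: Optional[StopVersion] = None
    stop_fraction: float = 0.30
    mix_version_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    upper_rt_limit: float = 1300.0
    max_intereffector_delay: float = 200.0
    hold_after_stop: float = 1300.0
    staircase_start: float = 50.0
    staircase_step: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_fraction < 1.0:
            raise ConfigError(f"stop_fraction must lie in (0, 1), got {self.stop_fraction}")
        if not math.isclose(sum(self.mix_version_fractions), 1.0, abs_tol=1e-9):
            raise ConfigError("mix_version_fractions must sum to 1")
        for name in ("upper_rt_limit", "max_intereffector_delay", "hold_after_stop",
                     "staircase_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.staircase_start < 0:
            raise ConfigError("staircase_start must be non-negative")
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")


@dataclass(frozen=True)
class StaircaseState:
    """State of one adaptive SSD tracker (one-up/one-down, fixed step)."""

    current_ssd: float
    step: float = 50.0
    floor: float = 0.0
    ceiling: float = 1300.0

    def __post_init__(self) -> None:
        if not (self.floor <= self.current_ssd <= self.ceiling):
            raise InvalidStateError(
                f"SSD {self.current_ssd} outside [{self.floor}, {self.ceiling}]")


def next_ssd(state: StaircaseState, outcome: TrialOutcome | str) -> StaircaseState:
    """Advance the staircase after a stop trial.

    A Stop Correct trial makes stopping harder (SSD + step); a Stop Error
    trial makes it easier (SSD - step).  The result is clipped to the
    tracker's [floor, ceiling].  Aborted trials must not be passed here: they
    do not advance the staircase.
    """
    if not math.isfinite(state.current_ssd):
        raise InvalidStateError("staircase SSD is not finite")
    outcome = TrialOutcome(outcome)
    if outcome is TrialOutcome.CORRECT:
        ssd = state.current_ssd + state.step
    elif outcome is TrialOutcome.ERROR:
        ssd = state.current_ssd - state.step
    else:
        raise ValueError("staircase updates only on correct/error outcomes")
    ssd = min(max(ssd, state.floor), state.ceiling)
    return replace(state, current_ssd=ssd)


def classify_trial(
    version: Optional[StopVersion],
    wrist_moved: bool,
    foot_moved: bool,
    wrist_rt: Optional[float],
    foot_rt: Optional[float],
    config: SessionConfig,
    ssd: Optional[float] = None,
) -> TrialOutcome:
    """Classify a trial as correct / error / aborted.

    Rules:

    * no-stop (``version`` is None): correct iff both effectors moved, each
      within the upper RT limit, and no more than ``max_intereffector_delay``
      apart; otherwise aborted.
    * stop_both: correct iff neither effector moved within
      ``hold_after_stop`` of the Stop signal (movements after the hold window
      do not count); otherwise error.  Without an ``ssd`` any movement
      counts as an error.
    * stop_wrist: error iff the wrist moved (at any time); correct iff the
      wrist held and the foot moved within the upper RT limit; otherwise
      aborted.  stop_foot is symmetric.
    """
    if wrist_moved and wrist_rt is None:
        raise MalformedTrialError("wrist moved but wrist_rt is missing")
    if foot_moved and foot_rt is None:
        raise MalformedTrialError("foot moved but foot_rt is missing")

    if version is None:  # no-stop trial
        if not (wrist_moved and foot_moved):
            return TrialOutcome.ABORTED
        if wrist_rt > config.upper_rt_limit or foot_rt > config.upper_rt_limit:
            return TrialOutcome.ABORTED
        if abs(wrist_rt - foot_rt) > config.max_intereffector_delay:
            return TrialOutcome.ABORTED
        return TrialOutcome.CORRECT

    version = StopVersion(version)
    if version is StopVersion.STOP_BOTH:
        deadline = None if ssd is None else ssd + config.hold_after_stop
        for moved, rt in ((wrist_moved, wrist_rt), (foot_moved, foot_rt)):
            if moved and (deadline is None or rt <= deadline):
                return TrialOutcome.ERROR
        return TrialOutcome.CORRECT

    stopped_moved, moving_moved, moving_rt = (
        (wrist_moved, foot_moved, foot_rt)
        if version is StopVersion.STOP_WRIST
        else (foot_moved, wrist_moved, wrist_rt)
    )
    if stopped_moved:
        return TrialOutcome.ERROR
    if moving_moved and moving_rt <= config.upper_rt_limit:
        return TrialOutcome.CORRECT
    return TrialOutcome.ABORTED


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    """Split ``total`` into integer counts proportional to ``fractions``.

    Deterministic: remainders are assigned by descending fractional part,
    ties broken by position.
    """
    ideal = [total * f for f in fractions]
    base = [int(math.floor(x)) for x in ideal]
    short = total - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def allocate_trials(config: SessionConfig) -> list[tuple[str, Optional[StopVersion]]]:
    """Build the seeded trial sequence of a session with exact type counts.

    The number of stop trials is ``round(n_trials * stop_fraction)`` (not a
    Bernoulli draw), mix sessions split the stop trials across the three
    versions by largest-remainder rounding, and the final order is a
    permutation drawn from ``numpy.random.default_rng(config.seed)``.
    """
    n_stop = int(math.floor(config.n_trials * config.stop_fraction + 0.5))
    trials: list[tuple[str, Optional[StopVersion]]]
    trials = [(NO_STOP, None)] * (config.n_trials - n_stop)
    if config.condition is TaskCondition.BLOCK:
        if config.block_version is None:
            raise ConfigError("block sessions require block_version")
        trials += [(STOP, StopVersion(config.block_version))] * n_stop
    else:
        counts = _largest_remainder(n_stop, config.mix_version_fractions)
        for version, k in zip(StopVersion, counts):
            trials += [(STOP, version)] * k
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


# ---------------------------------------------------------------------------
# Trial-table I/O (delimited text, one row per trial)
# ---------------------------------------------------------------------------

TRIAL_TABLE_COLUMNS = [
    "participant_id", "condition", "session_version", "trial_index",
    "trial_type", "stop_version", "stop_order", "ssd",
    "wrist_moved", "foot_moved",
    "wrist_mus_rt", "foot_mus_rt", "wrist_rt", "foot_rt", "outcome",
]

_TIME_COLUMNS = ["ssd", "wrist_mus_rt", "foot_mus_rt", "wrist_rt", "foot_rt"]


def write_trial_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV; times carry one decimal, missing as empty."""
    out = frame.copy()
    for col in _TIME_COLUMNS:
        if col in out.columns:
            out[col] = out[col].round(1)
    out.to_csv(path, index=False, float_format="%.1f")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read a trial table, validating the schema.

    Raises :class:`MalformedTrialError` naming the first missing column.
    """
    frame = pd.read_csv(path)
    for col in TRIAL_TABLE_COLUMNS:
        if col not in frame.columns:
            raise MalformedTrialError(f"trial table is missing column {col!r}")
    for col in ("wrist_moved", "foot_moved"):
        frame[col] = frame[col].astype(bool)
    return frame
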