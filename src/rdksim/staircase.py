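"""Adaptive 1-up/1-down staircase for the angle-matching task.

The line angle steps by 3° against the observer's response, a reversal is
scored when the response switches sign, the staircase stops after seven
reversals and the matching angle is the mean of the last four reversal
angles.  If the observer keeps driving the line angle into the zero floor,
the staircase terminates with a matching angle of zero (the observer can no
longer see two separate directions).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from .observer import Choice
from .stimulus import ValidationError

__all__ = [
    "StaircaseConfig",
    "TrialRecord",
    "StaircaseResult",
    "Termination",
    "initial_line_angle",
    "next_angle",
    "is_reversal",
    "run_staircase",
    "condition_estimate",
]


class Termination(enum.Enum):
    REVERSALS_COMPLETE = "reversals_complete"
    ZERO_FLOOR = "zero_floor"
    MAX_TRIALS = "max_trials"


@dataclass(frozen=True)
class StaircaseConfig:
    step: float = 3.0  # degrees per trial
    reversals_to_stop: int = 7
    reversals_to_average: int = 4
    init_halfwidth: float = 20.0  # start angle drawn within ±this of Δ
    max_trials: int = 200  # safety cap; human staircases ran 15-30 trials
    zero_floor_run: int = 5  # consecutive down-responses at 0 that end the run
    #: "switch": the reversal angle is the line angle of the trial on which
    #: the response switch is scored (the turnaround extreme).
    #: "pre_switch": the line angle of the preceding trial.
    reversal_bookkeeping: str = "switch"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("step must be positive")
        if self.reversals_to_average > self.reversals_to_stop:
            raise ValidationError("reversals_to_average must be <= reversals_to_stop")
        if self.max_trials < self.reversals_to_stop:
            raise ValidationError("max_trials must be >= reversals_to_stop")
        if self.reversal_bookkeeping not in ("switch", "pre_switch"):
            raise ValidationError(
                f"unknown reversal_bookkeeping {self.reversal_bookkeeping!r}"
            )


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    line_angle: float
    choice: Choice
    is_reversal: bool


@dataclass
class StaircaseResult:
    trials: list[TrialRecord]
    reversal_angles: list[float]
    matching_angle: float
    termination: Termination
    delta: float = field(default=float("nan"))
    coherence: float = field(default=float("nan"))

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def initial_line_angle(
    delta: float, config: StaircaseConfig, rng: np.random.Generator
) -> float:
    """Random start angle within ±init_halfwidth of the veridical separation,
    clipped at zero."""
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    lo = max(0.0, delta - config.init_halfwidth)
    hi = delta + config.init_halfwidth
    return float(rng.uniform(lo, hi))


def next_angle(current: float, choice: Choice, config: StaircaseConfig) -> float:
    """Step the line angle against the response, clipping at zero."""
    if current < 0:
        raise ValidationError("line angle must be >= 0")
    if choice is Choice.LINES_WIDER:
        return max(0.0, current - config.step)
    return current + config.step


def is_reversal(previous_choice: Choice | None, current_choice: Choice) -> bool:
    """A reversal is a switch between wider and narrower reports; the first
    trial never scores one."""
    if previous_choice is None:
        return False
    return previous_choice is not current_choice


def run_staircase(
    delta: float,
    coherence: float,
    observer,
    config: StaircaseConfig,
    rng: np.random.Generator,
) -> StaircaseResult:
    """Run one full staircase for a (Δ, coherence) condition.

    ``observer`` must expose ``trial_percept(delta, coherence, rng)`` and
    ``decide(percept, line_angle, rng)``.  Each trial draws a fresh percept
    of the moving stimulus and compares it with the current line angle.
    """
    line = initial_line_angle(delta, config, rng)
    trials: list[TrialRecord] = []
    reversal_angles: list[float] = []
    prev_choice: Choice | None = None
    prev_line = line
    floor_run = 0

    for t in range(config.max_trials):
        percept = observer.trial_percept(delta, coherence, rng)
        choice = observer.decide(percept, line, rng)
        rev = is_reversal(prev_choice, choice)
        trials.append(TrialRecord(t, line, choice, rev))
        if rev:
            reversal_angles.append(
                line if config.reversal_bookkeeping == "switch" else prev_line
            )
            if len(reversal_angles) >= config.reversals_to_stop:
                matching = fmean(reversal_angles[-config.reversals_to_average :])
                return StaircaseResult(
                    trials, reversal_angles, matching,
                    Termination.REVERSALS_COMPLETE, delta, coherence,
                )
        # zero-floor rule: the observer keeps reporting the lines as wider
        # even at a zero-degree line angle, i.e. keeps driving downward
        if line == 0.0 and choice is Choice.LINES_WIDER:
            floor_run += 1
            if floor_run >= config.zero_floor_run:
                return StaircaseResult(
                    trials, reversal_angles, 0.0, Termination.ZERO_FLOOR,
                    delta, coherence,
                )
        else:
            floor_run = 0
        prev_choice = choice
        prev_line = line
        line = next_angle(line, choice, config)

    # safety cap reached: flagged, never silently averaged
    return StaircaseResult(
        trials, reversal_angles, float("nan"), Termination.MAX_TRIALS,
        delta, coherence,
    )


def condition_estimate(results: list[StaircaseResult]) -> float:
    """Perceived separation for one (subject, condition): the mean matching
    angle of the first four completed staircases."""
    if len(results) != 4:
        raise ValidationError(f"exactly 4 staircases are required, got {len(results)}")
    for r in results:
        if r.termination is Termination.MAX_TRIALS:
            raise ValidationError(
                "cannot average a staircase that hit the trial cap"
            )
    return fmean(r.matching_angle for r in results)
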