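"""Declarative experiment designs and the full simulated study loop.

Experiment 1 crosses direction separation {30°, 60°} with six coherence
levels from 50% to 100%; Experiment 2 crosses coherence {60%, 100%} with
eight separations from 15° to 120°.  Four subjects run four staircases per
condition; the tidy result table carries one row per staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ParametricObserver, ParametricObserverParams, draw_cohort
from .staircase import StaircaseConfig, Termination, run_staircase
from .stimulus import ValidationError

__all__ = [
    "ExperimentDesign",
    "ExperimentDataset",
    "design_experiment1",
    "design_experiment2",
    "run_experiment",
    "EXP1_COHERENCES",
    "EXP2_SEPARATIONS",
]

EXP1_COHERENCES = (0.50, 0.60, 0.70, 0.80, 0.90, 1.00)
#: Eight separations spanning 15°–120°, including the 25° effect peak.
EXP2_SEPARATIONS = (15.0, 25.0, 30.0, 45.0, 60.0, 90.0, 105.0, 120.0)

DATASET_COLUMNS = [
    "subject_id",
    "direction_separation",
    "coherence",
    "staircase_id",
    "matching_angle",
    "termination",
]


@dataclass(frozen=True)
class ExperimentDesign:
    name: str
    conditions: tuple[tuple[float, float], ...]  # (direction_separation, coherence)
    n_subjects: int = 4
    staircases_per_condition: int = 4
    #: staircases run and discarded before the recorded ones (the 2-3
    #: practice staircases human subjects needed; model observers do not
    #: learn, so the default is 0)
    practice_staircases: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise ValidationError("design must have at least one condition")
        for delta, coh in self.conditions:
            if not 0.0 <= coh <= 1.0:
                raise ValidationError(f"coherence {coh} outside [0, 1]")
            if delta < 0:
                raise ValidationError(f"negative separation {delta}")
        if self.n_subjects < 1 or self.staircases_per_condition < 1:
            raise ValidationError("n_subjects and staircases_per_condition must be >= 1")


@dataclass
class ExperimentDataset:
    """Tidy staircase-level results plus provenance."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"dataset table missing columns: {missing}")


def design_experiment1() -> ExperimentDesign:
    """Δ ∈ {30°, 60°} × coherence ∈ {0.5 … 1.0 in 0.1 steps}."""
    conditions = tuple(
        (delta, coh) for delta in (30.0, 60.0) for coh in EXP1_COHERENCES
    )
    return ExperimentDesign(name="experiment1", conditions=conditions)


def design_experiment2(separations: tuple[float, ...] = EXP2_SEPARATIONS) -> ExperimentDesign:
    """Coherence ∈ {0.6, 1.0} × eight separations from 15° to 120°."""
    conditions = tuple(
        (delta, coh) for coh in (0.60, 1.00) for delta in separations
    )
    return ExperimentDesign(name="experiment2", conditions=conditions)


def run_experiment(
    design: ExperimentDesign,
    cohort: list[ParametricObserverParams],
    staircase_config: StaircaseConfig | None = None,
    seed: int = 0,
) -> ExperimentDataset:
    """Run every (subject, condition, staircase) cell of a design.

    Each staircase gets its own child random stream derived from
    ``(seed, subject, condition, staircase)``, so any single staircase can
    be reproduced in isolation.
    """
    if len(cohort) != design.n_subjects:
        raise ValidationError(
            f"cohort size {len(cohort)} != design.n_subjects {design.n_subjects}"
        )
    config = staircase_config or StaircaseConfig()
    rows = []
    n_capped = 0
    for si, params in enumerate(cohort):
        observer = ParametricObserver(params)
        for ci, (delta, coh) in enumerate(design.conditions):
            for pk in range(design.practice_staircases):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), si, ci, 1000 + pk])
                )
                run_staircase(delta, coh, observer, config, rng)  # discarded
            for ki in range(design.staircases_per_condition):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), si, ci, ki])
                )
                result = run_staircase(delta, coh, observer, config, rng)
                if result.termination is Termination.MAX_TRIALS:
                    n_capped += 1
                rows.append(
                    {
                        "subject_id": f"S{si + 1}",
                        "direction_separation": delta,
                        "coherence": coh,
                        "staircase_id": ki + 1,
                        "matching_angle": result.matching_angle,
                        "termination": result.termination.value,
                        "n_trials": result.n_trials,
                    }
                )
    table = pd.DataFrame(rows)
    provenance = {
        "design": design.name,
        "seed": int(seed),
        "n_subjects": design.n_subjects,
        "staircases_per_condition": design.staircases_per_condition,
        "n_staircases_at_trial_cap": n_capped,
        "staircase_config": {
            "step": config.step,
            "reversals_to_stop": config.reversals_to_stop,
            "reversals_to_average": config.reversals_to_average,
            "init_halfwidth": config.init_halfwidth,
            "max_trials": config.max_trials,
            "zero_floor_run": config.zero_floor_run,
            "reversal_bookkeeping": config.reversal_bookkeeping,
        },
    }
    return ExperimentDataset(table=table, provenance=provenance)


def default_cohort(n_subjects: int = 4, seed: int = 0) -> list[ParametricObserverParams]:
    """Convenience wrapper: the default heterogeneous 4-subject cohort."""
    return draw_cohort(n_subjects, np.random.SeedSequence([int(seed), 987654321]))
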