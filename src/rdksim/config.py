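"""Run configuration, seed bookkeeping and dataset round-tripping.

A run is fully described by a YAML config (stimulus/observer/staircase
overrides, design, root seed); every output artifact echoes the effective
config and the seed so any result file can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .experiment import DATASET_COLUMNS, ExperimentDataset
from .observer import ParametricObserverParams
from .staircase import StaircaseConfig
from .stimulus import StimulusSpec, ValidationError

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_dataset",
    "read_dataset",
    "save_cohort",
    "load_cohort",
]

_STIMULUS_OVERRIDE_KEYS = {
    f.name for f in fields(StimulusSpec) if f.name not in ("direction_separation", "metadata")
}
_OBSERVER_KEYS = {f.name for f in fields(ParametricObserverParams)}
_STAIRCASE_KEYS = {f.name for f in fields(StaircaseConfig)}


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated experiment."""

    design: str = "experiment1"
    seed: int = 0
    n_subjects: int = 4
    staircases_per_condition: int = 4
    output_dir: str = "results"
    verbosity: int = 1
    stimulus: dict = field(default_factory=dict)
    observer: dict = field(default_factory=dict)
    staircase: dict = field(default_factory=dict)
    cohort_file: str | None = None

    def observer_params(self) -> ParametricObserverParams:
        return ParametricObserverParams(**self.observer)

    def staircase_config(self) -> StaircaseConfig:
        return StaircaseConfig(**self.staircase)


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) in {section!r}: {', '.join(sorted(unknown))}"
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected and
    out-of-range values raise errors naming the offending key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    top_allowed = {f.name for f in fields(RunConfig)}
    _check_keys("config", raw, top_allowed)
    cfg = RunConfig(**raw)

    _check_keys("stimulus", cfg.stimulus, _STIMULUS_OVERRIDE_KEYS)
    _check_keys("observer", cfg.observer, _OBSERVER_KEYS)
    _check_keys("staircase", cfg.staircase, _STAIRCASE_KEYS)
    if "coherence" in cfg.stimulus and not 0.0 <= cfg.stimulus["coherence"] <= 1.0:
        raise ValidationError(
            f"coherence must lie in [0, 1], got {cfg.stimulus['coherence']}"
        )
    # probe constructions surface range errors with the field name
    StimulusSpec(direction_separation=30.0, coherence=1.0,
                 **{k: v for k, v in cfg.stimulus.items() if k != "coherence"})
    cfg.observer_params()
    cfg.staircase_config()
    if cfg.design not in ("experiment1", "experiment2"):
        raise ValidationError(f"unknown design {cfg.design!r}")
    return cfg


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


# --------------------------------------------------------------------------
# Dataset CSV + JSON sidecar
# --------------------------------------------------------------------------


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_dataset(dataset: ExperimentDataset, csv_path) -> Path:
    """Write the tidy staircase table as CSV with a JSON provenance sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    dataset.table.to_csv(csv_path, index=False)
    _sidecar_path(csv_path).write_text(json.dumps(dataset.provenance, indent=2))
    return csv_path


def read_dataset(csv_path) -> ExperimentDataset:
    """Re-read a dataset written by :func:`write_dataset`, checking the schema."""
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    expected = set(DATASET_COLUMNS) | {"n_trials"}
    extra = sorted(set(table.columns) - expected)
    missing = sorted(set(DATASET_COLUMNS) - set(table.columns))
    if extra or missing:
        raise ValidationError(
            f"dataset schema mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    provenance = {}
    sidecar = _sidecar_path(csv_path)
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return ExperimentDataset(table=table, provenance=provenance)


# --------------------------------------------------------------------------
# Staircase trial logs
# --------------------------------------------------------------------------


def write_staircase_log(
    result, csv_path, subject: str = "S1", staircase_id: int = 1, seed=None
) -> Path:
    """Verbose per-trial log of one staircase: CSV plus a JSON sidecar with
    the matching angle, termination cause and seed."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "subject": subject,
            "delta_deg": result.delta,
            "coherence": result.coherence,
            "staircase_id": staircase_id,
            "trial": [t.trial_index for t in result.trials],
            "line_angle_deg": [t.line_angle for t in result.trials],
            "choice": [t.choice.value for t in result.trials],
            "is_reversal": [t.is_reversal for t in result.trials],
        }
    )
    table.to_csv(csv_path, index=False)
    sidecar = {
        "matching_angle": result.matching_angle,
        "termination": result.termination.value,
        "reversal_angles": result.reversal_angles,
        "seed": seed,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=2))
    return csv_path


# --------------------------------------------------------------------------
# Observer cohorts
# --------------------------------------------------------------------------


def save_cohort(cohort: list[ParametricObserverParams], path, seed=None) -> None:
    """Write per-subject observer parameters (with the generating seed)."""
    payload = {
        "seed": seed,
        "subjects": [dataclasses.asdict(p) for p in cohort],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_cohort(path) -> list[ParametricObserverParams]:
    payload = yaml.safe_load(Path(path).read_text())
    subjects = payload.get("subjects", [])
    if not subjects:
        raise ValidationError("cohort file lists no subjects")
    out = []
    for entry in subjects:
        _check_keys("cohort subject", entry, _OBSERVER_KEYS)
        out.append(ParametricObserverParams(**entry))
    return out
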