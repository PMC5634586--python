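"""CSV writers/readers and the JSON run-configuration schema."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import TRAJECTORY_COLUMNS, Trajectory
from .parameters import ModelConstants, ParameterSet
from .scenarios import ScenarioId

__all__ = [
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_frame",
]

_FLOAT_FMT = "%.6f"


def write_trajectory(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as fixed-point CSV (6 decimals, LF, UTF-8)."""
    frame = t.frame[TRAJECTORY_COLUMNS]
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_trajectory(path: str | Path) -> Trajectory:
    frame = pd.read_csv(path)
    return Trajectory(frame)


def write_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Generic CSV writer used for heat-map, comparison and ensemble tables."""
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONSTANT_KEYS = {
    "dt",
    "reference_fev1_at_20",
    "reference_decline",
    "plateau_end_age",
    "sim_start_age",
    "sim_end_age",
    "tau_activity",
    "tau_impact",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated single-run configuration: one parameter source + overrides."""

    scenario: int | None = None
    patient: int | None = None
    params_path: str | None = None
    constants: ModelConstants = field(default_factory=ModelConstants)
    out: str | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.scenario, self.patient, self.params_path)
            if s is not None
        ]
        if len(sources) != 1:
            raise ValueError(
                "exactly one parameter source (scenario, patient or params) "
                "is required"
            )

    def parameter_set(self) -> ParameterSet:
        from .scenarios import builtin_parameters

        if self.scenario is not None:
            return builtin_parameters(ScenarioId("scenario", self.scenario))
        if self.patient is not None:
            return builtin_parameters(ScenarioId("patient", self.patient))
        return ParameterSet.from_json(self.params_path)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration.

    Recognized keys: ``scenario``, ``patient``, ``params`` (path to a
    ParameterSet JSON), ``constants`` (ModelConstants overrides), ``out``,
    ``verbose``.  Unknown keys are rejected by name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("run config must be a JSON object")
    known = {"scenario", "patient", "params", "constants", "out", "verbose"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    overrides = raw.get("constants", {})
    if not isinstance(overrides, dict):
        raise ValueError("config key 'constants' must be an object")
    bad = set(overrides) - _CONSTANT_KEYS
    if bad:
        raise ValueError(f"unknown constants key(s): {sorted(bad)}")
    constants = ModelConstants(**overrides)
    return RunConfig(
        scenario=raw.get("scenario"),
        patient=raw.get("patient"),
        params_path=raw.get("params"),
        constants=constants,
        out=raw.get("out"),
        verbose=bool(raw.get("verbose", False)),
    )
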