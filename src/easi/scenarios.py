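"""Built-in canonical parameterizations and cross-scenario summary tables.

Six clinical scenarios explore single-parameter departures from a
susceptible continuous smoker (quitting at 45 or 65, persistent
inflammation despite quitting, abnormal early-life lung development, poor
symptom perception).  Four patient profiles illustrate how very different
life-course trajectories can converge on the same symptom burden at age 50,
including a never-smoker with low early-adult lung function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .model import Trajectory, simulate
from .parameters import ModelConstants, ParameterSet

__all__ = [
    "ScenarioId",
    "SCENARIO_NAMES",
    "PATIENT_COUNT",
    "builtin_parameters",
    "decade_heatmap",
    "compare_at",
]

SCENARIO_NAMES = {
    1: "Susceptible continuous smoker",
    2: "Susceptible quitter at 45 years",
    3: "Susceptible quitter at 65 years",
    4: "Persistent inflammation despite quitting",
    5: "Abnormal lung development",
    6: "Poor perceiver",
}
PATIENT_COUNT = 4

HEATMAP_VARIABLES = ("exposure_frac", "activity", "fev1_pct_ref", "impact")


@dataclass(frozen=True)
class ScenarioId:
    """Identifier of a built-in parameterization."""

    kind: Literal["scenario", "patient"]
    index: int

    def __post_init__(self) -> None:
        if self.kind == "scenario":
            if self.index not in SCENARIO_NAMES:
                raise ValueError(f"scenario index must be 1..6, got {self.index}")
        elif self.kind == "patient":
            if not 1 <= self.index <= PATIENT_COUNT:
                raise ValueError(f"patient index must be 1..4, got {self.index}")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    def __str__(self) -> str:
        return f"{self.kind}-{self.index}"


_BASE_SCENARIO = dict(
    age_smoking_onset=15.0,
    max_exposure=1.5,
    time_to_max_exposure=5.0,
    age_quitting=None,
    time_to_complete_quitting=None,
    activity_trigger=0.3,
    activity_slope=2.0,
    persistence_after_quitting=None,
    normal_decline=30.0,
    severity_trigger=0.10,
    severity_slope=2.0,
    max_decline=100.0,
    fev1_at_20=4.0,
    impact_trigger=0.80,
    impact_slope=2.0,
    smoker=True,
)

_SCENARIO_OVERRIDES: dict[int, dict] = {
    1: {},
    2: dict(age_quitting=45.0, time_to_complete_quitting=1.0,
            persistence_after_quitting=0.0),
    3: dict(age_quitting=65.0, time_to_complete_quitting=1.0,
            persistence_after_quitting=0.0),
    4: dict(age_quitting=45.0, time_to_complete_quitting=1.0,
            persistence_after_quitting=0.40),
    5: dict(fev1_at_20=3.0),
    6: dict(impact_trigger=0.50),
}

_PATIENTS: dict[int, dict] = {
    1: dict(
        age_smoking_onset=15.0, max_exposure=3.0, time_to_max_exposure=1.0,
        age_quitting=40.0, time_to_complete_quitting=1.0,
        activity_trigger=0.3, activity_slope=2.0,
        persistence_after_quitting=0.25,
        normal_decline=12.0, severity_trigger=0.20, severity_slope=2.0,
        max_decline=75.0, fev1_at_20=3.0,
        impact_trigger=0.90, impact_slope=1.0, smoker=True,
    ),
    2: dict(
        age_smoking_onset=16.0, max_exposure=2.0, time_to_max_exposure=2.5,
        age_quitting=45.0, time_to_complete_quitting=1.0,
        activity_trigger=0.1, activity_slope=3.5,
        persistence_after_quitting=0.20,
        normal_decline=35.0, severity_trigger=0.10, severity_slope=2.5,
        max_decline=90.0, fev1_at_20=4.0,
        impact_trigger=0.85, impact_slope=3.0, smoker=True,
    ),
    3: dict(
        age_smoking_onset=17.0, max_exposure=1.5, time_to_max_exposure=2.0,
        age_quitting=None, time_to_complete_quitting=None,
        activity_trigger=0.1, activity_slope=3.5,
        persistence_after_quitting=None,
        normal_decline=20.0, severity_trigger=0.30, severity_slope=1.0,
        max_decline=75.0, fev1_at_20=4.5,
        impact_trigger=1.15, impact_slope=2.0, smoker=True,
    ),
    # Never-smoker with impaired early-life lung development; the activity
    # trigger is stored but inert because exposure is identically zero.
    4: dict(
        age_smoking_onset=None, max_exposure=0.0, time_to_max_exposure=None,
        age_quitting=None, time_to_complete_quitting=None,
        activity_trigger=0.35, activity_slope=2.0,
        persistence_after_quitting=None,
        normal_decline=20.0, severity_trigger=0.20, severity_slope=1.0,
        max_decline=60.0, fev1_at_20=2.8,
        impact_trigger=0.85, impact_slope=2.0, smoker=False,
    ),
}


def builtin_parameters(id: ScenarioId | str) -> ParameterSet:
    """Exact parameter values of a built-in scenario or patient profile."""
    if isinstance(id, str):
        kind, _, idx = id.partition("-")
        id = ScenarioId(kind, int(idx))
    if id.kind == "scenario":
        return ParameterSet(**{**_BASE_SCENARIO, **_SCENARIO_OVERRIDES[id.index]})
    return ParameterSet(**_PATIENTS[id.index])


def decade_heatmap(t: Trajectory, max_exposure: float | None = None) -> pd.DataFrame:
    """Decade-age summary table of the four stage variables.

    Samples the trajectory at the grid point nearest each decade age within
    its span; exposure is normalized by the maximal daily dose so every
    column lies in [0, 1] except ``fev1_pct_ref``.
    """
    ages = t.ages
    decades = [a for a in range(20, 90, 10) if ages[0] - 1e-9 <= a <= ages[-1] + 1e-9]
    if not decades:
        raise ValueError("trajectory covers no decade ages")
    if max_exposure is None:
        max_exposure = float(t.frame["exposure_packs_day"].max())
    rows = []
    for a in decades:
        s = t.at_age(a)
        frac = s["exposure_packs_day"] / max_exposure if max_exposure > 0 else 0.0
        rows.append(
            {
                "decade_age": a,
                "exposure_frac": frac,
                "activity": s["activity"],
                "fev1_pct_ref": s["fev1_pct_ref"],
                "impact": s["impact"],
            }
        )
    return pd.DataFrame(rows)


def compare_at(
    ids: list[ScenarioId | str],
    age: float,
    variable: str,
    constants: ModelConstants | None = None,
) -> pd.DataFrame:
    """One value of ``variable`` per built-in id, sampled at ``age``.

    ``variable`` is a trajectory column or a heat-map alias
    (``exposure_frac``, ``E``, ``A``, ``I``).
    """
    aliases = {
        "E": "exposure_packs_day",
        "A": "activity",
        "I": "impact",
        "fev1": "fev1_L",
    }
    column = aliases.get(variable, variable)
    rows = []
    for id_ in ids:
        p = builtin_parameters(id_)
        t = simulate(p, constants)
        if column == "exposure_frac":
            e = t.value(age, "exposure_packs_day")
            value = e / p.max_exposure if p.max_exposure > 0 else 0.0
        else:
            value = t.value(age, column)
        rows.append({"id": str(id_), "age": age, "variable": variable,
                     "value": value})
    frame = pd.DataFrame(rows)
    frame.attrs["spread"] = float(np.ptp(frame["value"])) if len(frame) else 0.0
    return frame
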