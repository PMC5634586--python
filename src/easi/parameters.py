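"""Parameter containers for an individual natural-history simulation.

A simulated individual is fully described by 15 inputs spanning the four
stages of the cascade: smoking exposure (onset, dose, quitting), the
inflammatory-activity dose response, the FEV1-decline (severity) dose
response, and the symptom-impact dose response.  Never-smokers set the
exposure block to ``None`` and keep the downstream blocks, which is how an
individual with impaired lung development but no smoking history is encoded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any

__all__ = ["ParameterSet", "ModelConstants"]


@dataclass(frozen=True)
class ParameterSet:
    """The 15 per-individual inputs of the simulator.

    Percent-valued quantities (persistence, severity trigger, impact trigger)
    are stored as fractions: a persistence of "40% of peak activity" is 0.40,
    an impact trigger of "80% of reference FEV1" is 0.80.  An impact trigger
    above 1.0 is legal (a hyper-perceiver reacts while still above reference).

    ``age_quitting`` is ``None`` for a non-quitter; the whole exposure block
    (onset, dose, ramp, quitting) is ``None`` for a never-smoker
    (``smoker=False``).
    """

    # Exposure block
    age_smoking_onset: float | None = 15.0     # years
    max_exposure: float = 1.5                  # packs/day
    time_to_max_exposure: float | None = 5.0   # years, 5%->95% ramp
    age_quitting: float | None = None          # years; None = non-quitter
    time_to_complete_quitting: float | None = None  # years, 95%->5% ramp
    # Activity block
    activity_trigger: float = 0.3              # packs/day
    activity_slope: float = 2.0
    persistence_after_quitting: float | None = None  # fraction of peak activity
    # Severity block
    normal_decline: float = 30.0               # ml/year, healthy initial-slope rate
    severity_trigger: float = 0.10             # fraction of maximal activity
    severity_slope: float = 2.0
    max_decline: float = 100.0                 # ml/year
    fev1_at_20: float = 4.0                    # liters
    # Impact block
    impact_trigger: float = 0.80               # fraction of reference FEV1
    impact_slope: float = 2.0
    smoker: bool = True

    def __post_init__(self) -> None:
        if self.smoker:
            if self.age_smoking_onset is None:
                raise ValueError("age_smoking_onset is required for a smoker")
            if self.max_exposure < 0:
                raise ValueError("max_exposure must be >= 0")
            if self.time_to_max_exposure is None or self.time_to_max_exposure <= 0:
                raise ValueError("time_to_max_exposure must be > 0 for a smoker")
            if self.age_quitting is not None:
                if self.age_quitting <= self.age_smoking_onset:
                    raise ValueError("age_quitting must exceed age_smoking_onset")
                if (
                    self.time_to_complete_quitting is None
                    or self.time_to_complete_quitting <= 0
                ):
                    raise ValueError(
                        "time_to_complete_quitting must be > 0 for a quitter"
                    )
        if not (self.max_decline >= self.normal_decline >= 0):
            raise ValueError("need max_decline >= normal_decline >= 0")
        if self.fev1_at_20 <= 0:
            raise ValueError("fev1_at_20 must be > 0")
        for name in ("activity_slope", "severity_slope", "impact_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.persistence_after_quitting is not None and not (
            0.0 <= self.persistence_after_quitting <= 1.0
        ):
            raise ValueError("persistence_after_quitting must lie in [0, 1]")
        if self.activity_trigger < 0 or self.severity_trigger < 0:
            raise ValueError("triggers must be >= 0")
        if self.impact_trigger <= 0:
            raise ValueError("impact_trigger must be > 0")

    # -- convenience ------------------------------------------------------
    @property
    def is_quitter(self) -> bool:
        return self.smoker and self.age_quitting is not None

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    # -- JSON interface ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        """Plain dict with snake_case keys; non-quitter -> null age_quitting."""
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "ParameterSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ModelConstants:
    """Simulation constants shared by every individual.

    ``dt`` is the Euler step of the integrator.  The reference (normal-lung)
    trajectory is anchored at ``reference_fev1_at_20`` liters, stays on a
    plateau until ``plateau_end_age`` and then declines at an initial-slope
    rate of ``reference_decline`` ml/yr.  ``tau_activity`` and ``tau_impact``
    are the relaxation times of the activity and impact stages.
    """

    dt: float = 0.2                    # years
    reference_fev1_at_20: float = 4.0  # liters
    reference_decline: float = 30.0    # ml/year
    plateau_end_age: float = 25.0      # years; decline starts here
    sim_start_age: float = 10.0        # years
    sim_end_age: float = 90.0          # years
    tau_activity: float = 1.0          # years
    tau_impact: float = 1.0            # years

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.sim_start_age < 20 <= self.plateau_end_age < self.sim_end_age):
            raise ValueError(
                "require sim_start_age < 20 <= plateau_end_age < sim_end_age"
            )
        if self.tau_activity <= 0 or self.tau_impact <= 0:
            raise ValueError("relaxation times must be > 0")
        if self.reference_fev1_at_20 <= 0:
            raise ValueError("reference_fev1_at_20 must be > 0")

    @property
    def n_steps(self) -> int:
        return round((self.sim_end_age - self.sim_start_age) / self.dt)

    def age_grid(self):
        import numpy as np

        ages = self.sim_start_age + self.dt * np.arange(self.n_steps + 1)
        return np.round(ages, 9)

    def replace(self, **changes: Any) -> "ModelConstants":
        return dataclasses.replace(self, **changes)
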