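"""Steady-state activation functions linking consecutive stages.

Each stage of the cascade converts the output of the stage above through a
sigmoid dose-response curve parameterized by a trigger (half-activation or
onset point) and a slope.  Two forms are used:

``logistic``
    The plain logistic 1/(1+exp(-slope*(x-trigger))), optionally mirrored
    (``decreasing``).  Used for symptom impact, which has a graded response
    on both sides of its trigger.

``gated``
    A thresholded, saturating response: exactly zero at and below the
    trigger, rising as 1-exp(-slope*d) with the signed distance d from the
    trigger, saturating toward 1.  Used for inflammatory activity (a
    never-smoker mounts no response at all) and for the activity-to-decline
    coupling (a fully quiescent lung declines at exactly the normal rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["ActivationSpec", "logistic", "gated", "activate"]

Form = Literal["logistic", "gated"]
Direction = Literal["increasing", "decreasing"]


@dataclass(frozen=True)
class ActivationSpec:
    """Trigger/slope/shape of one steady-state activation curve."""

    trigger: float
    slope: float
    form: Form = "logistic"
    direction: Direction = "increasing"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.form not in ("logistic", "gated"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _signed_distance(x, spec: ActivationSpec):
    d = np.asarray(x, dtype=float) - spec.trigger
    return d if spec.direction == "increasing" else -d


def logistic(x, spec: ActivationSpec):
    """Plain logistic response in [0, 1]; 0.5 exactly at the trigger."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to activation function")
    out = 1.0 / (1.0 + np.exp(-spec.slope * _signed_distance(x, spec)))
    return out if out.shape else float(out)


def gated(x, spec: ActivationSpec):
    """Thresholded saturating response: 0 at/below trigger, ->1 beyond it."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to activation function")
    d = _signed_distance(x, spec)
    out = np.where(d > 0.0, -np.expm1(-spec.slope * np.maximum(d, 0.0)), 0.0)
    return out if out.shape else float(out)


def activate(x, spec: ActivationSpec):
    """Evaluate ``spec`` on ``x`` (scalar or array); output always in [0, 1]."""
    return gated(x, spec) if spec.form == "gated" else logistic(x, spec)
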