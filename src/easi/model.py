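"""Core four-stage cascade and its fixed-step Euler integrator.

The cascade is strictly feed-forward: smoking Exposure E(t) drives
inflammatory Activity A(t), activity sets the rate of FEV1 decline
(Severity), and the FEV1 deficit relative to an age-matched reference
drives perceived symptom Impact I(t).

E(t) is a closed-form product of two logistics in time (smoking initiation
and cessation).  A(t) and I(t) are first-order linear relaxations toward
steady-state targets given by the activation curves in
:mod:`easi.activation`.  FEV1 obeys a first-order linear decline law

    dFEV1/dt = -rho(A) * FEV1,   rho(A) = decline_rate(A) / fev1_at_20,

so the tabulated ml/yr decline rates are initial-slope rates at the
individual's age-20 volume and the volume decays exponentially under a
sustained activity level.  All four equations are integrated together with
an explicit Euler scheme (default step 0.2 years).

A single trajectory and a population ensemble share the same vectorized
kernel; ``simulate`` is the batch-of-one case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationSpec, gated, logistic
from .parameters import ModelConstants, ParameterSet

__all__ = [
    "ModelState",
    "Trajectory",
    "SimulationError",
    "exposure_at",
    "activity_target",
    "decline_rate",
    "reference_fev1",
    "impact_target",
    "step",
    "simulate",
    "simulate_batch",
]

_LN19 = float(np.log(19.0))  # logistic ramps span 5% -> 95% over the stated duration

TRAJECTORY_COLUMNS = [
    "age",
    "exposure_packs_day",
    "pack_years",
    "activity",
    "fev1_L",
    "fev1_pct_ref",
    "impact",
]


class SimulationError(RuntimeError):
    """The model left its validity domain (e.g. FEV1 reached zero)."""


# ---------------------------------------------------------------------------
# Stage equations
# ---------------------------------------------------------------------------

def _exposure_arrays(age, onset, t_max, quit_age, t_quit, max_exposure):
    """Vectorized smoking exposure: product of onset and quitting logistics.

    The rising logistic covers [onset, onset + t_max] from 5% to 95% of the
    maximal dose; for quitters a mirrored falling logistic covers
    [quit_age, quit_age + t_quit].  Non-quitters are encoded with
    ``quit_age = +inf`` and never-smokers with ``max_exposure = 0``.
    """
    k_on = 2.0 * _LN19 / t_max
    on = 1.0 / (1.0 + np.exp(np.clip(-k_on * (age - (onset + 0.5 * t_max)),
                                     -700.0, 700.0)))
    k_off = 2.0 * _LN19 / t_quit
    off = 1.0 / (1.0 + np.exp(-np.clip(k_off * ((quit_age + 0.5 * t_quit) - age),
                                       -700.0, 700.0)))
    return max_exposure * on * off


def exposure_at(age: float, p: ParameterSet) -> float:
    """Daily smoking dose (packs/day) at ``age`` for one individual."""
    if not np.all(np.isfinite(age)):
        raise ValueError("non-finite age")
    if not p.smoker or p.max_exposure == 0.0:
        return 0.0 * np.asarray(age, dtype=float) + 0.0 if np.ndim(age) else 0.0
    quit_age = p.age_quitting if p.is_quitter else np.inf
    t_quit = p.time_to_complete_quitting if p.is_quitter else 1.0
    out = _exposure_arrays(
        np.asarray(age, dtype=float),
        p.age_smoking_onset,
        p.time_to_max_exposure,
        quit_age,
        t_quit,
        p.max_exposure,
    )
    return out if np.ndim(age) else float(out)


def activity_target(E, A_peak, p: ParameterSet):
    """Steady-state inflammatory activity for exposure ``E``.

    Exactly zero for an individual whose exposure never exceeded the
    trigger; once a peak activity has been reached, the target is floored at
    ``persistence_after_quitting * A_peak`` (residual inflammation after
    cessation).
    """
    spec = ActivationSpec(p.activity_trigger, p.activity_slope, form="gated")
    base = gated(E, spec)
    persistence = p.persistence_after_quitting or 0.0
    return np.maximum(base, persistence * np.asarray(A_peak, dtype=float))


def decline_rate(A, p: ParameterSet):
    """FEV1 decline rate in ml/yr as a function of activity ``A``.

    Normal rate at or below the severity trigger (a quiescent lung ages at
    the healthy rate), saturating toward the maximal rate as activity rises.
    """
    spec = ActivationSpec(p.severity_trigger, p.severity_slope, form="gated")
    return p.normal_decline + (p.max_decline - p.normal_decline) * gated(A, spec)


def reference_fev1(age, c: ModelConstants):
    """Age-matched normal-lung FEV1 (liters), the denominator of "% ref".

    Constant at ``reference_fev1_at_20`` through the plateau, then an
    exponential decay whose initial slope is ``reference_decline`` ml/yr —
    the same first-order law as the individual severity stage with activity
    pinned at zero.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < c.sim_start_age - 1e-9) or np.any(age > c.sim_end_age + 1e-9):
        raise ValueError("age outside the simulation window")
    rho0 = (c.reference_decline / 1000.0) / c.reference_fev1_at_20  # 1/yr
    years = np.maximum(age - c.plateau_end_age, 0.0)
    out = c.reference_fev1_at_20 * np.exp(-rho0 * years)
    return out if out.shape else float(out)


def impact_target(fev1_pct_ref, p: ParameterSet):
    """Steady-state symptom impact given FEV1 as a *fraction* of reference."""
    spec = ActivationSpec(
        p.impact_trigger, p.impact_slope, form="logistic", direction="decreasing"
    )
    return logistic(fev1_pct_ref, spec)


# ---------------------------------------------------------------------------
# State, single Euler step, trajectory container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of one simulated individual."""

    age: float            # years
    E: float              # packs/day
    pack_years: float     # cumulative dose
    A: float              # activity, fraction of maximum
    A_peak: float         # running maximum of A (persistence memory)
    fev1: float           # liters
    I: float              # impact, fraction of maximum


def step(s: ModelState, p: ParameterSet, c: ModelConstants) -> ModelState:
    """One explicit-Euler update of the full cascade, feed-forward in-step."""
    if s.age + c.dt > c.sim_end_age + 1e-9:
        raise ValueError("step would leave the simulation window")
    if s.fev1 <= 0:
        raise SimulationError("FEV1 is non-positive; model left validity domain")
    dt = c.dt
    a_new = s.A + dt * (float(activity_target(s.E, s.A_peak, p)) - s.A) / c.tau_activity
    a_new = min(max(a_new, 0.0), 1.0)
    c_new = s.pack_years + s.E * dt
    if s.age >= c.plateau_end_age - 1e-9:
        rho = (float(decline_rate(s.A, p)) / 1000.0) / p.fev1_at_20
        fev1_new = s.fev1 * (1.0 - dt * rho)
    else:
        fev1_new = s.fev1
    if fev1_new <= 0:
        raise SimulationError("FEV1 reached a non-positive value")
    pct = s.fev1 / float(reference_fev1(s.age, c))
    i_new = s.I + dt * (float(impact_target(pct, p)) - s.I) / c.tau_impact
    i_new = min(max(i_new, 0.0), 1.0)
    age_new = s.age + dt
    return ModelState(
        age=age_new,
        E=exposure_at(age_new, p),
        pack_years=c_new,
        A=a_new,
        A_peak=max(s.A_peak, a_new),
        fev1=fev1_new,
        I=i_new,
    )


class Trajectory:
    """Fixed-step life-course time series of one simulated individual.

    Wraps a DataFrame with columns ``age, exposure_packs_day, pack_years,
    activity, fev1_L, fev1_pct_ref, impact`` on a uniform age grid.
    """

    def __init__(self, frame: pd.DataFrame, constants: ModelConstants | None = None):
        missing = [col for col in TRAJECTORY_COLUMNS if col not in frame.columns]
        if missing:
            raise ValueError(f"trajectory frame missing column(s) {missing}")
        self.frame = frame.reset_index(drop=True)
        self.constants = constants

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy()

    def _row_index(self, age: float) -> int:
        ages = self.ages
        if age < ages[0] - 1e-9 or age > ages[-1] + 1e-9:
            raise ValueError(f"age {age} outside trajectory range")
        return int(np.argmin(np.abs(ages - age)))

    def at_age(self, age: float) -> pd.Series:
        """State sampled at the grid point nearest to ``age``."""
        return self.frame.iloc[self._row_index(age)]

    def value(self, age: float, column: str) -> float:
        return float(self.at_age(age)[column])


# ---------------------------------------------------------------------------
# Vectorized kernel
# ---------------------------------------------------------------------------

def _param_arrays(params: list[ParameterSet]) -> dict[str, np.ndarray]:
    def col(getter):
        return np.asarray([getter(p) for p in params], dtype=float)

    return {
        "onset": col(lambda p: p.age_smoking_onset if p.smoker else 0.0),
        "t_max": col(lambda p: p.time_to_max_exposure if p.smoker else 1.0),
        "quit_age": col(lambda p: p.age_quitting if p.is_quitter else np.inf),
        "t_quit": col(lambda p: p.time_to_complete_quitting if p.is_quitter else 1.0),
        "max_exposure": col(lambda p: p.max_exposure if p.smoker else 0.0),
        "activity_trigger": col(lambda p: p.activity_trigger),
        "activity_slope": col(lambda p: p.activity_slope),
        "persistence": col(lambda p: p.persistence_after_quitting or 0.0),
        "normal_decline": col(lambda p: p.normal_decline),
        "severity_trigger": col(lambda p: p.severity_trigger),
        "severity_slope": col(lambda p: p.severity_slope),
        "max_decline": col(lambda p: p.max_decline),
        "fev1_at_20": col(lambda p: p.fev1_at_20),
        "impact_trigger": col(lambda p: p.impact_trigger),
        "impact_slope": col(lambda p: p.impact_slope),
    }


def _gated_arr(x, trigger, slope):
    d = x - trigger
    return np.where(d > 0.0, -np.expm1(-slope * np.maximum(d, 0.0)), 0.0)


def simulate_batch(
    params: list[ParameterSet], c: ModelConstants | None = None
) -> dict[str, np.ndarray]:
    """Integrate many individuals at once on a shared age grid.

    Returns arrays of shape (n_ages, n_individuals) for each state column
    plus the 1-D ``age`` grid.  Raises :class:`SimulationError` naming the
    first offending individual if any FEV1 becomes non-positive.
    """
    c = c or ModelConstants()
    pa = _param_arrays(params)
    ages = c.age_grid()
    n_t, n = len(ages), len(params)
    dt = c.dt

    exposure = _exposure_arrays(
        ages[:, None], pa["onset"], pa["t_max"], pa["quit_age"], pa["t_quit"],
        pa["max_exposure"],
    )
    ref = np.asarray(reference_fev1(ages, c))

    A = np.zeros((n_t, n))
    C = np.zeros((n_t, n))
    fev1 = np.zeros((n_t, n))
    I = np.zeros((n_t, n))
    fev1[0] = pa["fev1_at_20"]
    a_peak = np.zeros(n)

    for k in range(n_t - 1):
        e_k = exposure[k]
        target_a = np.maximum(
            _gated_arr(e_k, pa["activity_trigger"], pa["activity_slope"]),
            pa["persistence"] * a_peak,
        )
        A[k + 1] = np.clip(A[k] + dt * (target_a - A[k]) / c.tau_activity, 0.0, 1.0)
        a_peak = np.maximum(a_peak, A[k + 1])
        C[k + 1] = C[k] + e_k * dt
        rate = pa["normal_decline"] + (pa["max_decline"] - pa["normal_decline"]) * (
            _gated_arr(A[k], pa["severity_trigger"], pa["severity_slope"])
        )
        rho = (rate / 1000.0) / pa["fev1_at_20"]
        if ages[k] >= c.plateau_end_age - 1e-9:
            fev1[k + 1] = fev1[k] * (1.0 - dt * rho)
        else:
            fev1[k + 1] = fev1[k]
        pct = fev1[k] / ref[k]
        target_i = 1.0 / (
            1.0 + np.exp(-pa["impact_slope"] * (pa["impact_trigger"] - pct))
        )
        I[k + 1] = np.clip(I[k] + dt * (target_i - I[k]) / c.tau_impact, 0.0, 1.0)

    if np.any(fev1 <= 0):
        bad = int(np.argwhere(fev1 <= 0)[0, 1])
        raise SimulationError(
            f"FEV1 reached a non-positive value for individual {bad}"
        )
    return {
        "age": ages,
        "exposure": exposure,
        "pack_years": C,
        "activity": A,
        "fev1": fev1,
        "fev1_pct_ref": 100.0 * fev1 / ref[:, None],
        "impact": I,
    }


def simulate(p: ParameterSet, c: ModelConstants | None = None) -> Trajectory:
    """Full life-course trajectory of one individual (batch-of-one kernel)."""
    c = c or ModelConstants()
    out = simulate_batch([p], c)
    frame = pd.DataFrame(
        {
            "age": out["age"],
            "exposure_packs_day": out["exposure"][:, 0],
            "pack_years": out["pack_years"][:, 0],
            "activity": out["activity"][:, 0],
            "fev1_L": out["fev1"][:, 0],
            "fev1_pct_ref": out["fev1_pct_ref"][:, 0],
            "impact": out["impact"][:, 0],
        }
    )
    return Trajectory(frame, constants=c)
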