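"""Seeded Monte Carlo ensembles of simulated individuals.

A population is described by per-parameter truncated-normal sampling
distributions (center, coefficient of variation, truncation bounds), by
default centered on the susceptible-continuous-smoker values with CV 0.15.
Ensembles are bitwise reproducible: each draw's generator is derived from
(seed, draw_index), so draw ``i`` is the same whether sampled alone or as
part of a cohort.

The ensemble summary carries per-age mean/SD of FEV1, the per-individual
mean adult decline, the FEV1 distribution at any grid age and the fraction
of the cohort below a lower limit of normality (LLN).  The LLN is a
configurable fraction of the internal reference trajectory (default 0.80),
a synthetic stand-in for published spirometric reference equations.

``calibrate`` adjusts the dispersion hyperparameters (optionally also the
centers) by seeded derivative-free random search so that the ensemble
mean/SD curves and the mean adult decline match user-supplied targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SimulationError, reference_fev1, simulate_batch
from .parameters import ModelConstants, ParameterSet
from .scenarios import builtin_parameters

__all__ = [
    "ParamDist",
    "PopulationSpec",
    "EnsembleSummary",
    "CalibrationResult",
    "default_population",
    "sample_parameters",
    "run_ensemble",
    "fraction_below_lln",
    "calibrate",
]

# Numeric parameters that vary across a population (the quitting block is
# absent because the default centers describe a persistent smoker).
_VARYING = (
    "age_smoking_onset",
    "time_to_max_exposure",
    "max_exposure",
    "activity_trigger",
    "activity_slope",
    "normal_decline",
    "severity_trigger",
    "severity_slope",
    "max_decline",
    "fev1_at_20",
    "impact_trigger",
    "impact_slope",
)

# Hard validity bounds enforced on every draw, tighter of these and the
# ±3·CV default truncation.
_HARD_BOUNDS = {
    "age_smoking_onset": (5.0, 40.0),
    "time_to_max_exposure": (0.5, 30.0),
    "max_exposure": (0.05, 10.0),
    "activity_trigger": (0.01, 5.0),
    "activity_slope": (0.1, 20.0),
    "normal_decline": (1.0, 200.0),
    "severity_trigger": (0.01, 0.99),
    "severity_slope": (0.1, 20.0),
    "max_decline": (1.0, 400.0),
    "fev1_at_20": (0.5, 8.0),
    "impact_trigger": (0.05, 2.0),
    "impact_slope": (0.1, 20.0),
}


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal sampling law for one parameter."""

    center: float
    cv: float = 0.15
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if (
            self.lower is not None
            and self.upper is not None
            and self.lower > self.upper
        ):
            raise ValueError("impossible truncation bounds (lower > upper)")

    def bounds(self) -> tuple[float, float]:
        sd = abs(self.center) * self.cv
        lo = self.center - 3.0 * sd if self.lower is None else self.lower
        hi = self.center + 3.0 * sd if self.upper is None else self.upper
        return lo, hi


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling description of a simulated cohort."""

    n_models: int = 1000
    seed: int = 0
    smoker: bool = True
    dists: dict[str, ParamDist] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        unknown = set(self.dists) - set(_VARYING)
        if unknown:
            raise ValueError(f"unknown parameter(s) in dists: {sorted(unknown)}")

    def replace(self, **changes) -> "PopulationSpec":
        return dataclasses.replace(self, **changes)


def default_population(
    n_models: int = 1000, seed: int = 0, smoker: bool = True, cv: float = 0.15
) -> PopulationSpec:
    """Cohort spec centered on the continuous-smoker scenario values."""
    center = builtin_parameters("scenario-1")
    dists = {}
    for name in _VARYING:
        c = float(getattr(center, name))
        lo, hi = _HARD_BOUNDS[name]
        sd = c * cv
        dists[name] = ParamDist(
            c, cv, lower=max(lo, c - 3 * sd), upper=min(hi, c + 3 * sd)
        )
    return PopulationSpec(n_models=n_models, seed=seed, smoker=smoker, dists=dists)


def _draw_truncnorm(rng: np.random.Generator, dist: ParamDist) -> float:
    if dist.cv == 0.0:
        return dist.center
    lo, hi = dist.bounds()
    sd = abs(dist.center) * dist.cv
    for _ in range(1000):
        x = rng.normal(dist.center, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(dist.center, lo), hi))


def sample_parameters(spec: PopulationSpec, draw_index: int) -> ParameterSet:
    """Deterministic draw ``draw_index`` of the cohort described by ``spec``."""
    rng = np.random.default_rng([spec.seed, draw_index])
    values = {}
    # Draw every varying parameter in a fixed order so the stream is stable.
    for name in _VARYING:
        dist = spec.dists.get(name)
        values[name] = (
            _draw_truncnorm(rng, dist) if dist is not None
            else float(getattr(builtin_parameters("scenario-1"), name))
        )
    if values["normal_decline"] > values["max_decline"]:
        values["normal_decline"] = values["max_decline"]
    if not spec.smoker:
        values["age_smoking_onset"] = None
        values["time_to_max_exposure"] = None
        values["max_exposure"] = 0.0
    return ParameterSet(
        smoker=spec.smoker,
        age_quitting=None,
        time_to_complete_quitting=None,
        persistence_after_quitting=None,
        **values,
    )


@dataclass
class EnsembleSummary:
    """Cohort-level statistics of a simulated population."""

    spec: PopulationSpec
    constants: ModelConstants
    by_age: pd.DataFrame          # age, mean_fev1_L, sd_fev1_L, mean_pct_ref, frac_below_lln
    declines_ml_yr: np.ndarray    # per-individual mean adult decline
    fev1: np.ndarray              # (n_ages, n_models) liters
    lln_fraction: float = 0.80

    @property
    def ages(self) -> np.ndarray:
        return self.by_age["age"].to_numpy()

    @property
    def mean_decline_ml_yr(self) -> float:
        return float(np.mean(self.declines_ml_yr))

    def fev1_at(self, age: float) -> np.ndarray:
        """FEV1 distribution (liters) across the cohort at a grid age."""
        idx = int(np.argmin(np.abs(self.ages - age)))
        if abs(self.ages[idx] - age) > self.constants.dt:
            raise ValueError(f"age {age} outside the simulated range")
        return self.fev1[idx]


def run_ensemble(
    spec: PopulationSpec,
    constants: ModelConstants | None = None,
    lln_fraction: float = 0.80,
) -> EnsembleSummary:
    """Simulate every draw of ``spec`` and aggregate cohort statistics.

    The per-individual mean adult decline is the chord slope of FEV1 between
    the end of the plateau and age 80 (ml/yr).
    """
    c = constants or ModelConstants()
    params = []
    for i in range(spec.n_models):
        try:
            params.append(sample_parameters(spec, i))
        except ValueError as exc:
            raise ValueError(f"draw {i}: {exc}") from exc
    try:
        out = simulate_batch(params, c)
    except SimulationError as exc:
        raise SimulationError(f"ensemble simulation failed: {exc}") from exc
    ages = out["age"]
    fev1 = out["fev1"]
    ref = np.asarray(reference_fev1(ages, c))
    i_plateau = int(np.argmin(np.abs(ages - c.plateau_end_age)))
    age_late = min(80.0, c.sim_end_age)
    i_late = int(np.argmin(np.abs(ages - age_late)))
    span = ages[i_late] - ages[i_plateau]
    declines = (fev1[i_plateau] - fev1[i_late]) / span * 1000.0  # ml/yr
    lln = lln_fraction * ref[:, None]
    by_age = pd.DataFrame(
        {
            "age": ages,
            "mean_fev1_L": fev1.mean(axis=1),
            "sd_fev1_L": fev1.std(axis=1, ddof=0),
            "mean_pct_ref": out["fev1_pct_ref"].mean(axis=1),
            "frac_below_lln": (fev1 < lln).mean(axis=1),
        }
    )
    return EnsembleSummary(
        spec=spec,
        constants=c,
        by_age=by_age,
        declines_ml_yr=declines,
        fev1=fev1,
        lln_fraction=lln_fraction,
    )


def fraction_below_lln(
    summary: EnsembleSummary, age: float, lln_fraction: float | None = None
) -> float:
    """Share of the cohort whose FEV1 at ``age`` falls below the LLN."""
    frac = summary.lln_fraction if lln_fraction is None else lln_fraction
    lln = frac * float(reference_fev1(age, summary.constants))
    return float(np.mean(summary.fev1_at(age) < lln))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Outcome of a dispersion-calibration search."""

    spec: PopulationSpec
    loss: float
    initial_loss: float
    improved: bool
    n_evaluations: int
    message: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CalibrationResult(loss={self.loss:.4g}, improved={self.improved}, "
            f"n_evaluations={self.n_evaluations})"
        )


def _ensemble_loss(
    spec: PopulationSpec,
    targets: pd.DataFrame | None,
    decline_target: float | None,
    constants: ModelConstants,
    n_eval: int,
    eval_seed: int,
) -> float:
    summary = run_ensemble(
        spec.replace(n_models=n_eval, seed=eval_seed), constants
    )
    loss = 0.0
    if targets is not None and len(targets):
        ages = summary.ages
        for _, row in targets.iterrows():
            idx = int(np.argmin(np.abs(ages - row["age"])))
            loss += (summary.by_age["mean_fev1_L"].iloc[idx] - row["mean_fev1_L"]) ** 2
            if "sd_fev1_L" in targets.columns and np.isfinite(row["sd_fev1_L"]):
                loss += (summary.by_age["sd_fev1_L"].iloc[idx] - row["sd_fev1_L"]) ** 2
    if decline_target is not None:
        loss += ((summary.mean_decline_ml_yr - decline_target) / 1000.0) ** 2 * max(
            1, 0 if targets is None else len(targets)
        )
    return float(loss)


def calibrate(
    spec: PopulationSpec,
    targets: pd.DataFrame | None = None,
    decline_target: float | None = None,
    budget: int = 200,
    n_eval: int = 200,
    seed: int = 0,
    vary_centers: bool = False,
    constants: ModelConstants | None = None,
) -> CalibrationResult:
    """Seeded random search over dispersion (and optionally center) values.

    ``targets`` is a frame with columns ``age, mean_fev1_L[, sd_fev1_L]``;
    ``decline_target`` is a mean adult decline in ml/yr.  The search
    perturbs the per-parameter CVs multiplicatively (log-normal proposals
    with a decaying step), evaluating each candidate on a reduced ensemble
    with a fixed evaluation seed so the loss surface is deterministic.
    """
    if (targets is None or not len(targets)) and decline_target is None:
        raise ValueError("calibration needs at least one target")
    c = constants or ModelConstants()
    rng = np.random.default_rng([seed, 2**20])
    eval_seed = seed
    names = sorted(spec.dists)

    def evaluate(s: PopulationSpec) -> float:
        return _ensemble_loss(s, targets, decline_target, c, n_eval, eval_seed)

    best = spec
    best_loss = initial_loss = evaluate(spec)
    n_evals = 1
    improved = False
    for k in range(budget):
        step_size = 0.5 * (0.1 / 0.5) ** (k / max(1, budget - 1))
        dists = dict(best.dists)
        for name in names:
            d = dists[name]
            cv = d.cv * float(np.exp(rng.normal(0.0, step_size)))
            cv = float(np.clip(cv, 0.0, 1.0))
            center = d.center
            if vary_centers:
                center = d.center * float(np.exp(rng.normal(0.0, 0.5 * step_size)))
            lo, hi = _HARD_BOUNDS.get(name, (None, None))
            sd = abs(center) * cv
            dists[name] = ParamDist(
                center,
                cv,
                lower=None if lo is None else max(lo, center - 3 * sd),
                upper=None if hi is None else min(hi, center + 3 * sd),
            )
        candidate = best.replace(dists=dists)
        try:
            loss = evaluate(candidate)
        except (ValueError, SimulationError):
            continue
        n_evals += 1
        if loss < best_loss:
            best, best_loss, improved = candidate, loss, True
    message = (
        "improved on the initial spec"
        if improved
        else "search budget exhausted without improvement; returning input spec"
    )
    return CalibrationResult(
        spec=best,
        loss=best_loss,
        initial_loss=initial_loss,
        improved=improved,
        n_evaluations=n_evals,
        message=message,
    )
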