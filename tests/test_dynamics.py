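"""Cascade dynamics: stage couplings, Euler step, relaxation and isolation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from easi import (
    ModelConstants,
    ModelState,
    ParameterSet,
    activity_target,
    builtin_parameters,
    decline_rate,
    impact_target,
    reference_fev1,
    simulate,
    step,
)


class TestActivityTarget:
    def test_never_exposed_is_zero(self, scenario1):
        assert activity_target(0.0, 0.0, scenario1) == 0.0

    def test_persistence_floor_after_quitting(self):
        # 40% residual inflammation of a peak activity of 0.9
        p = builtin_parameters("scenario-4")
        assert float(activity_target(0.0, 0.9, p)) == pytest.approx(0.36)

    def test_saturates_close_to_one_at_full_dose(self, scenario1):
        value = float(activity_target(1.5, 0.0, scenario1))
        assert value == pytest.approx(1.0 - math.exp(-2.4))
        assert 0.9 < value < 1.0


class TestDeclineRate:
    def test_quiescent_lung_declines_at_normal_rate(self, scenario1):
        assert float(decline_rate(0.0, scenario1)) == pytest.approx(30.0)
        # anywhere at or below the severity trigger
        assert float(decline_rate(0.10, scenario1)) == pytest.approx(30.0)

    def test_saturates_at_maximal_rate(self, scenario1):
        p = scenario1.replace(severity_slope=50.0)
        assert float(decline_rate(1.0, p)) == pytest.approx(100.0, abs=0.01)

    def test_gated_closed_form(self, scenario1):
        expected = 30.0 + 70.0 * (1.0 - math.exp(-2.0 * (0.917 - 0.10)))
        assert float(decline_rate(0.917, scenario1)) == pytest.approx(expected)

    def test_bounded_by_normal_and_max(self, scenario1):
        rates = [float(decline_rate(a, scenario1)) for a in np.linspace(0, 1, 21)]
        assert all(30.0 <= r <= 100.0 for r in rates)


class TestReferenceFev1:
    def test_anchor_at_20(self, constants):
        assert reference_fev1(20.0, constants) == pytest.approx(4.0)

    def test_plateau_holds_to_25(self, constants):
        assert reference_fev1(25.0, constants) == pytest.approx(4.0)

    def test_exponential_decline_closed_form(self, constants):
        # 4 * exp(-(30/4000) * 55) after 55 post-plateau years
        assert reference_fev1(80.0, constants) == pytest.approx(2.648, abs=1e-3)

    def test_age_out_of_range_rejected(self, constants):
        with pytest.raises(ValueError):
            reference_fev1(95.0, constants)


class TestImpactTarget:
    def test_closed_form_at_low_lung_function(self, scenario1):
        assert float(impact_target(0.45, scenario1)) == pytest.approx(
            1 / (1 + math.exp(-0.7))
        )

    def test_midpoint_at_trigger(self, scenario1):
        assert float(impact_target(0.80, scenario1)) == pytest.approx(0.5)

    def test_poor_perceiver_reports_less_at_same_deficit(self, scenario1):
        poor = builtin_parameters("scenario-6")  # trigger 0.50
        assert float(impact_target(0.80, poor)) < float(
            impact_target(0.80, scenario1)
        )


class TestEulerStep:
    def test_quiet_young_state_only_ages(self, never_smoker, constants):
        s = ModelState(age=12.0, E=0.0, pack_years=0.0, A=0.0, A_peak=0.0,
                       fev1=4.0, I=0.0)
        s2 = step(s, never_smoker, constants)
        assert s2.age == pytest.approx(12.2)
        assert (s2.E, s2.pack_years, s2.A, s2.fev1) == (0.0, 0.0, 0.0, 4.0)

    def test_step_matches_vectorized_kernel(self, scenario1, constants):
        """Iterating the scalar step reproduces the batch trajectory."""
        t = simulate(scenario1, constants)
        s = ModelState(
            age=constants.sim_start_age,
            E=float(t.frame["exposure_packs_day"].iloc[0]),
            pack_years=0.0, A=0.0, A_peak=0.0,
            fev1=scenario1.fev1_at_20, I=0.0,
        )
        for k in range(1, len(t)):
            s = step(s, scenario1, constants)
            row = t.frame.iloc[k]
            assert s.fev1 == pytest.approx(row["fev1_L"], abs=1e-12)
            assert s.A == pytest.approx(row["activity"], abs=1e-12)
            assert s.I == pytest.approx(row["impact"], abs=1e-12)
            assert s.pack_years == pytest.approx(row["pack_years"], abs=1e-12)

    def test_step_outside_window_rejected(self, scenario1, constants):
        s = ModelState(age=90.0, E=0.0, pack_years=0.0, A=0.0, A_peak=0.0,
                       fev1=3.0, I=0.0)
        with pytest.raises(ValueError):
            step(s, scenario1, constants)

    def test_rapid_activity_onset_in_continuous_smoker(self, scenario1):
        """Sustained smoking triggers near-maximal inflammation before 25."""
        t = simulate(scenario1)
        a25 = t.value(25.0, "activity")
        a_ss = float(activity_target(1.5, 0.0, scenario1))
        assert a25 > 0.9 * a_ss


class TestRelaxationOracle:
    def test_euler_tracks_exponential_relaxation(self, constants):
        """Under constant exposure the Euler activity matches the continuous
        first-order relaxation within 1% once transients have passed (5 tau)."""
        # exposure held at the plateau dose throughout the simulated window
        p = builtin_parameters("scenario-1").replace(age_smoking_onset=-50.0)
        t = simulate(p, constants)
        target = float(activity_target(p.max_exposure, 0.0, p))
        elapsed = t.ages - constants.sim_start_age
        closed = target * (1.0 - np.exp(-elapsed / constants.tau_activity))
        late = elapsed >= 5.0 * constants.tau_activity
        assert np.max(np.abs(t.frame["activity"].to_numpy()[late] - closed[late])) <= 0.01

    def test_activity_reaches_target_after_five_tau(self, constants):
        p = builtin_parameters("scenario-1").replace(age_smoking_onset=-50.0)
        t = simulate(p, constants)
        target = float(activity_target(p.max_exposure, 0.0, p))
        assert t.value(constants.sim_start_age + 5.0, "activity") == pytest.approx(
            target, abs=0.01
        )


class TestFeedForwardIsolation:
    def test_impact_parameters_do_not_touch_upstream(self, scenario1):
        base = simulate(scenario1)
        tweaked = simulate(scenario1.replace(impact_trigger=0.5, impact_slope=7.0))
        for col in ("exposure_packs_day", "pack_years", "activity", "fev1_L",
                    "fev1_pct_ref"):
            assert np.array_equal(base.frame[col].to_numpy(),
                                  tweaked.frame[col].to_numpy())

    def test_severity_parameters_do_not_touch_exposure_or_activity(self, scenario1):
        base = simulate(scenario1)
        tweaked = simulate(
            scenario1.replace(normal_decline=10.0, max_decline=150.0,
                              severity_slope=5.0)
        )
        for col in ("exposure_packs_day", "pack_years", "activity"):
            assert np.array_equal(base.frame[col].to_numpy(),
                                  tweaked.frame[col].to_numpy())


@st.composite
def valid_parameters(draw):
    smoker = draw(st.booleans())
    quitter = smoker and draw(st.booleans())
    onset = draw(st.floats(11, 30)) if smoker else None
    return ParameterSet(
        smoker=smoker,
        age_smoking_onset=onset,
        max_exposure=draw(st.floats(0.1, 4)) if smoker else 0.0,
        time_to_max_exposure=draw(st.floats(0.5, 10)) if smoker else None,
        age_quitting=draw(st.floats(onset + 5, 80)) if quitter else None,
        time_to_complete_quitting=draw(st.floats(0.5, 5)) if quitter else None,
        activity_trigger=draw(st.floats(0.05, 1.0)),
        activity_slope=draw(st.floats(0.5, 6)),
        persistence_after_quitting=draw(st.floats(0, 1)) if quitter else None,
        normal_decline=draw(st.floats(5, 50)),
        severity_trigger=draw(st.floats(0.02, 0.6)),
        severity_slope=draw(st.floats(0.5, 6)),
        max_decline=draw(st.floats(60, 200)),
        fev1_at_20=draw(st.floats(2, 6)),
        impact_trigger=draw(st.floats(0.3, 1.3)),
        impact_slope=draw(st.floats(0.5, 6)),
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(p=valid_parameters())
def test_trajectory_invariants_hold_for_any_valid_individual(p):
    """Fractions stay in [0,1], FEV1 stays positive and never rises after the
    plateau, and cumulative pack-years never decrease."""
    c = ModelConstants()
    t = simulate(p, c)
    f = t.frame
    assert np.all((f["activity"] >= 0) & (f["activity"] <= 1))
    assert np.all((f["impact"] >= 0) & (f["impact"] <= 1))
    assert np.all(f["fev1_L"] > 0)
    assert np.all(np.diff(f["pack_years"]) >= -1e-12)
    post = f["age"] >= c.plateau_end_age
    assert np.all(np.diff(f.loc[post, "fev1_L"]) <= 1e-12)
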