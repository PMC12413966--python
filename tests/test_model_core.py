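"""Unit and property tests for the two-compartment disposition engine."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poppk import (
    ConcentrationProfile,
    DoseEvent,
    PKParameters,
    UnsupportedOperationError,
    ValidationError,
    auc,
    concentration_profile,
    concentrations_at,
    micro_constants,
    terminal_halflife,
)

param_sets = st.builds(
    PKParameters,
    cl=st.floats(1.0, 30.0),
    q=st.floats(1.0, 100.0),
    vc=st.floats(10.0, 200.0),
    vp=st.floats(10.0, 200.0),
)


class TestMicroConstants:
    def test_matches_polynomial_root_oracle(self, ref_params):
        """alpha/beta agree with a generic root-finder on the disposition quadratic."""
        mr = micro_constants(ref_params)
        assert mr.k10 == pytest.approx(ref_params.cl / ref_params.vc)
        assert mr.k12 == pytest.approx(ref_params.q / ref_params.vc)
        assert mr.k21 == pytest.approx(ref_params.q / ref_params.vp)
        roots = np.roots([1.0, -(mr.k10 + mr.k12 + mr.k21), mr.k10 * mr.k21])
        alpha_ref, beta_ref = np.max(roots), np.min(roots)
        assert mr.alpha == pytest.approx(alpha_ref, rel=1e-12)
        assert mr.beta == pytest.approx(beta_ref, rel=1e-12)
        # frozen values for the reference parameter set
        assert mr.k10 == pytest.approx(0.1408, abs=1e-4)
        assert mr.k21 == pytest.approx(1.5253, abs=1e-4)
        assert mr.alpha == pytest.approx(2.5973, abs=1e-4)
        assert mr.beta == pytest.approx(0.0827, abs=1e-4)

    def test_one_compartment_limit(self):
        """q = 0 disables the distribution pathway; dominant rate is k10."""
        mr = micro_constants(PKParameters(cl=5.0, q=0.0, vc=40.0, vp=30.0))
        assert mr.k12 == 0.0
        assert mr.k21 == 0.0
        assert mr.alpha == pytest.approx(0.125)
        assert mr.beta == 0.0

    def test_rejects_nonlinear_model(self, ref_params):
        with pytest.raises(UnsupportedOperationError):
            micro_constants(ref_params.replace(vm=50.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=param_sets)
    def test_vieta_identities(self, params):
        """alpha*beta = k10*k21 and alpha+beta = k10+k12+k21."""
        mr = micro_constants(params)
        assert mr.alpha * mr.beta == pytest.approx(mr.k10 * mr.k21, rel=1e-12)
        assert mr.alpha + mr.beta == pytest.approx(mr.k10 + mr.k12 + mr.k21, rel=1e-12)
        assert mr.alpha >= mr.beta > 0


class TestConcentrationProfile:
    def test_bolus_initial_concentration(self, ref_params):
        """C(0+) = amount / vc for a bolus at t = 0."""
        prof = concentration_profile(ref_params, [DoseEvent.from_mg(0.0, 10.0)], [0.0, 1.0])
        assert prof.conc[0] == pytest.approx(10000.0 / 49.86, rel=1e-12)

    def test_monoexponential_limit_is_exact(self):
        """With q = 0 the central curve is exactly (D/vc) exp(-cl/vc t)."""
        params = PKParameters(cl=5.0, q=0.0, vc=40.0, vp=30.0)
        t = np.linspace(0.0, 30.0, 50)
        prof = concentration_profile(params, [DoseEvent(0.0, 8000.0)], t)
        expected = 8000.0 / 40.0 * np.exp(-0.125 * t)
        np.testing.assert_allclose(prof.conc, expected, rtol=1e-12)

    def test_closed_form_matches_ode(self, ref_params, weekly_doses):
        """Closed-form and ODE solutions agree to 1e-6 relative over [0, 56] d."""
        t = np.linspace(0.0, 56.0, 225)
        closed = concentration_profile(ref_params, weekly_doses, t, method="closed").conc
        numeric = concentration_profile(ref_params, weekly_doses, t, method="ode").conc
        mask = closed > 1e-9
        np.testing.assert_allclose(numeric[mask], closed[mask], rtol=1e-6)

    def test_superposition_of_single_doses(self, ref_params, weekly_doses):
        """Multi-dose profile equals the sum of time-shifted single-dose profiles."""
        t = np.linspace(0.0, 40.0, 173)
        multi = concentration_profile(ref_params, weekly_doses, t).conc
        total = np.zeros_like(t)
        for d in weekly_doses:
            total += concentration_profile(ref_params, [d], t).conc
        np.testing.assert_allclose(multi, total, rtol=1e-10, atol=1e-300)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params=param_sets, scale=st.floats(0.1, 50.0))
    def test_dose_proportionality(self, params, scale):
        """Scaling all dose amounts by c scales every concentration by exactly c."""
        doses = [DoseEvent(0.0, 5000.0), DoseEvent(7.0, 2500.0)]
        scaled = [DoseEvent(d.time, d.amount * scale) for d in doses]
        t = np.array([0.5, 3.0, 7.0, 10.0, 21.0])
        base = concentrations_at(params, doses, t)
        np.testing.assert_allclose(concentrations_at(params, scaled, t), base * scale, rtol=1e-12)

    def test_mass_conservation_without_elimination(self):
        """cl = vm = 0: drug only redistributes, so C equilibrates at D/(vc+vp)."""
        params = PKParameters(cl=0.0, q=30.0, vc=50.0, vp=25.0)
        dose = 7500.0
        t = np.array([0.0, 0.5, 2.0, 10.0, 50.0, 200.0])
        prof = concentration_profile(params, [DoseEvent(0.0, dose)], t, method="ode")
        assert prof.conc[0] == pytest.approx(dose / 50.0, rel=1e-6)
        assert np.all(prof.conc <= dose / 50.0 + 1e-9)
        assert prof.conc[-1] == pytest.approx(dose / (50.0 + 25.0), rel=1e-6)

    def test_times_before_first_dose_are_zero(self, ref_params):
        prof = concentration_profile(ref_params, [DoseEvent(5.0, 1000.0)], [0.0, 1.0, 4.9, 5.0])
        assert np.all(prof.conc[:3] == 0.0)
        assert prof.conc[3] > 0

    def test_unsorted_times_rejected(self, ref_params):
        with pytest.raises(ValidationError):
            concentration_profile(ref_params, [DoseEvent(0.0, 1000.0)], [1.0, 0.5])

    def test_infusion_matches_ode_and_is_continuous(self, ref_params):
        """A 1-day zero-order infusion agrees with the ODE integrator."""
        doses = [DoseEvent(time=0.0, amount=10000.0, duration=1.0)]
        t = np.linspace(0.0, 14.0, 113)
        closed = concentration_profile(ref_params, doses, t, method="closed").conc
        numeric = concentration_profile(ref_params, doses, t, method="ode").conc
        mask = closed > 1e-9
        np.testing.assert_allclose(numeric[mask], closed[mask], rtol=1e-6)
        assert closed[0] == 0.0  # infusion starts at zero concentration

    def test_nonlinear_elimination_speeds_up_low_concentrations(self, ref_params):
        """Adding a Michaelis-Menten term strictly lowers the profile."""
        doses = [DoseEvent.from_mg(0.0, 10.0)]
        t = np.linspace(0.5, 28.0, 30)
        linear = concentrations_at(ref_params, doses, t)
        nonlinear = concentrations_at(ref_params.replace(vm=500.0, km=10.0), doses, t)
        assert np.all(nonlinear < linear)


class TestAUC:
    def test_infinite_auc_is_dose_over_clearance(self, ref_params, weekly_doses):
        """AUC(0, inf) = total dose / cl for the linear model (1e-8 relative)."""
        total_dose = sum(d.amount for d in weekly_doses)
        value = auc(ref_params, 0.0, np.inf, doses=weekly_doses, method="analytic")
        assert value == pytest.approx(total_dose / ref_params.cl, rel=1e-8)

    def test_numeric_default_grid_matches_analytic(self, ref_params, weekly_doses):
        exact = auc(ref_params, 0.0, 28.0, doses=weekly_doses, method="analytic")
        approx = auc(ref_params, 0.0, 28.0, doses=weekly_doses, method="numeric")
        assert approx == pytest.approx(exact, rel=1e-3)

    def test_trapezoid_convergence_is_second_order(self, ref_params):
        """Halving the grid step shrinks the trapezoid error ~4-fold."""
        doses = [DoseEvent.from_mg(0.0, 10.0)]
        exact = auc(ref_params, 0.5, 28.0, doses=doses, method="analytic")
        err = [
            abs(auc(ref_params, 0.5, 28.0, doses=doses, method="numeric",
                    grid_per_28_days=g) - exact)
            for g in (250, 500)
        ]
        assert err[0] / err[1] == pytest.approx(4.0, rel=0.25)

    def test_profile_trapezoid_mode(self, ref_params):
        doses = [DoseEvent.from_mg(0.0, 10.0)]
        t = np.linspace(0.0, 28.0, 4001)
        prof = concentration_profile(ref_params, doses, t)
        exact = auc(ref_params, 0.0, 28.0, doses=doses, method="analytic")
        assert auc(prof, 0.0, 28.0) == pytest.approx(exact, rel=1e-3)

    def test_infusion_analytic_auc(self, ref_params):
        """Analytic infusion AUC agrees with dense trapezoid integration."""
        doses = [DoseEvent(0.0, 10000.0, duration=2.0)]
        exact = auc(ref_params, 0.0, 28.0, doses=doses, method="analytic")
        approx = auc(ref_params, 0.0, 28.0, doses=doses, method="numeric",
                     grid_per_28_days=20000)
        assert approx == pytest.approx(exact, rel=1e-5)
        assert auc(ref_params, 0.0, np.inf, doses=doses) == pytest.approx(
            10000.0 / ref_params.cl, rel=1e-8
        )

    def test_analytic_mode_rejects_nonlinear(self, ref_params):
        with pytest.raises(UnsupportedOperationError):
            auc(ref_params.replace(vm=100.0), 0.0, 28.0,
                doses=[DoseEvent(0.0, 1000.0)], method="analytic")

    def test_invalid_windows_rejected(self, ref_params):
        with pytest.raises(ValidationError):
            auc(ref_params, 5.0, 5.0, doses=[DoseEvent(0.0, 1000.0)])
        with pytest.raises(ValidationError):
            auc(ref_params, -1.0, 5.0, doses=[DoseEvent(0.0, 1000.0)])


class TestTerminalHalflife:
    def test_reference_value(self, ref_params):
        """ln 2 / beta ~ 8.38 days for the reference antibody parameters."""
        mr = micro_constants(ref_params)
        assert terminal_halflife(ref_params) == pytest.approx(math.log(2) / mr.beta)
        assert terminal_halflife(ref_params) == pytest.approx(8.38, abs=0.01)

    def test_one_compartment_limit(self):
        params = PKParameters(cl=5.0, q=0.0, vc=40.0, vp=30.0)
        assert terminal_halflife(params) == pytest.approx(math.log(2) / 0.125)

    def test_halving_clearance_lengthens_halflife(self, ref_params):
        assert terminal_halflife(ref_params.replace(cl=3.51)) > terminal_halflife(ref_params)

    def test_rejects_nonlinear(self, ref_params):
        with pytest.raises(UnsupportedOperationError):
            terminal_halflife(ref_params.replace(vm=10.0))


def test_profile_type_rejects_bad_grids():
    with pytest.raises(ValidationError):
        ConcentrationProfile(np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]))
    with pytest.raises(ValidationError):
        ConcentrationProfile(np.array([0.0, 1.0]), np.array([1.0]))


def test_parameter_validation():
    with pytest.raises(ValidationError):
        PKParameters(cl=-1.0, q=1.0, vc=10.0, vp=10.0)
    with pytest.raises(ValidationError):
        PKParameters(cl=1.0, q=1.0, vc=0.0, vp=10.0)
    with pytest.raises(ValidationError):
        DoseEvent(time=0.0, amount=0.0)
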