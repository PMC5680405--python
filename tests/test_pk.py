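"""Two-compartment elimination kinetics: simulation, fitting, ISF flux."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cedsim.errors import ParameterError, UnderDeterminedError
from cedsim.pk import (
    IsfFlowModel,
    PKDataset,
    TwoCompartmentParams,
    dominant_elimination_rate,
    fit_two_compartment,
    half_life,
    isf_flux_elimination,
    peripheral_amount,
    simulate_two_compartment,
)
from cedsim.synthetic import DEFAULT_TRUE_PARAMS, PkSimConfig, generate_pk_dataset

REF = TwoCompartmentParams(k10=3.72e-2, k12=7.12e-4, k21=3.81e-3, initial_amount=15.0)


def _ode_oracle(params, times, a0):
    """Independent stiff-ODE integration of the compartment system."""

    def rhs(_t, y):
        a1, a2 = y
        return [
            -(params.k10 + params.k12) * a1 + params.k21 * a2,
            params.k12 * a1 - params.k21 * a2,
        ]

    sol = solve_ivp(
        rhs, (0.0, max(times)), [a0, 0.0], t_eval=times, rtol=1e-11, atol=1e-14
    )
    return sol.y[0]


class TestSimulate:
    def test_one_compartment_limit_is_pure_exponential(self):
        p = TwoCompartmentParams(k10=0.05, k12=0.0, k21=0.0, initial_amount=2.0)
        t = np.linspace(0, 100, 7)
        np.testing.assert_allclose(
            simulate_two_compartment(p, t), 2.0 * np.exp(-0.05 * t), rtol=1e-12
        )

    def test_matches_numerical_ode_integration(self):
        times = np.array([24.0, 72.0, 168.0, 336.0, 672.0])
        analytic = simulate_two_compartment(REF, times)
        numeric = _ode_oracle(REF, times, REF.initial_amount)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-8)

    def test_total_mass_accounting(self):
        # central + peripheral + eliminated = dose at all times
        t = np.linspace(0.0, 500.0, 40)
        a1 = simulate_two_compartment(REF, t)
        a2 = peripheral_amount(REF, t)
        # eliminated = k10 * integral(a1): trapezoid over each [0, ti]
        def eliminated(ti):
            grid = np.linspace(0.0, ti, 4001)
            return REF.k10 * np.trapezoid(simulate_two_compartment(REF, grid), grid)

        elim = np.array([eliminated(ti) for ti in t])
        np.testing.assert_allclose(a1 + a2 + elim, REF.initial_amount, rtol=1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            TwoCompartmentParams(k10=-0.1, k12=0.0, k21=0.0)
        with pytest.raises(ParameterError):
            simulate_two_compartment(REF, [-1.0])


class TestFit:
    def test_noise_free_round_trip(self):
        ds = generate_pk_dataset(PkSimConfig(noise_model="none"))
        fit = fit_two_compartment(
            ds, TwoCompartmentParams(k10=1e-2, k12=1e-3, k21=1e-3)
        )
        assert fit.converged
        for name in ("k10", "k12", "k21"):
            true = getattr(DEFAULT_TRUE_PARAMS, name)
            assert getattr(fit, name) == pytest.approx(true, rel=1e-4)

    def test_single_exponential_data_gives_vanishing_k12(self):
        mono = TwoCompartmentParams(k10=3.72e-2, k12=0.0, k21=0.0)
        ds = generate_pk_dataset(PkSimConfig(true_params=mono, noise_model="none"))
        fit = fit_two_compartment(
            ds, TwoCompartmentParams(k10=1e-2, k12=1e-3, k21=1e-3)
        )
        assert fit.k10 == pytest.approx(3.72e-2, rel=1e-6)
        assert fit.k12 < 1e-8

    def test_too_few_time_points_is_under_determined(self):
        import pandas as pd

        df = pd.DataFrame(
            {"time_h": [24.0, 48.0, 96.0], "amount_ug": [1.0, 0.5, 0.2], "dose_ug": 15.0}
        )
        with pytest.raises(UnderDeterminedError):
            fit_two_compartment(
                PKDataset(df), TwoCompartmentParams(k10=1e-2, k12=1e-3, k21=1e-3)
            )

    def test_reports_standard_errors_under_noise(self):
        ds = generate_pk_dataset(PkSimConfig(noise_cv=0.10, seed=7))
        fit = fit_two_compartment(
            ds, TwoCompartmentParams(k10=1e-2, k12=1e-3, k21=1e-3)
        )
        assert fit.standard_errors is not None
        assert all(se > 0 for se in fit.standard_errors)


class TestRatesAndHalfLife:
    def test_dominant_rate_is_k10(self):
        assert dominant_elimination_rate(REF) == REF.k10

    def test_warns_when_exchange_competes_with_elimination(self):
        p = TwoCompartmentParams(k10=0.01, k12=0.01, k21=0.001)
        with pytest.warns(UserWarning, match="k12/k10"):
            assert dominant_elimination_rate(p) == 0.01

    @pytest.mark.parametrize(
        "k, expected",
        [(3.72e-2, 18.63), (np.log(2.0), 1.0), (3.40e-2, 20.39)],
    )
    def test_half_life_values(self, k, expected):
        assert half_life(k) == pytest.approx(expected, abs=0.01)

    def test_half_life_rejects_nonpositive_rate(self):
        with pytest.raises(ParameterError):
            half_life(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(k=st.floats(1e-6, 10.0))
    def test_half_life_times_rate_is_ln2(self, k):
        assert half_life(k) * k == pytest.approx(np.log(2.0), rel=1e-12)


class TestIsfFlux:
    def test_rat_brain_reference_numbers(self):
        q, v, k = isf_flux_elimination(IsfFlowModel(0.17, 1.8, 0.3))
        assert q == pytest.approx(0.306, abs=1e-9)
        assert v == pytest.approx(540.0, abs=1e-9)
        assert k == pytest.approx(3.40e-2, abs=1e-4)

    def test_rate_independent_of_brain_mass(self):
        _, _, k1 = isf_flux_elimination(IsfFlowModel(0.17, 1.8, 0.3))
        _, _, k2 = isf_flux_elimination(IsfFlowModel(0.17, 3.6, 0.3))
        assert k1 == pytest.approx(k2, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        outflow=st.floats(0.01, 1.0),
        mass=st.floats(0.5, 10.0),
        phi=st.floats(0.05, 0.6),
    )
    def test_scaling_laws(self, outflow, mass, phi):
        _, _, k = isf_flux_elimination(IsfFlowModel(outflow, mass, phi))
        _, _, k_double_outflow = isf_flux_elimination(IsfFlowModel(2 * outflow, mass, phi))
        assert k_double_outflow == pytest.approx(2 * k, rel=1e-12)
        _, _, k_double_phi = isf_flux_elimination(
            IsfFlowModel(outflow, mass, min(2 * phi, 0.99))
        )
        assert k_double_phi == pytest.approx(k * phi / min(2 * phi, 0.99), rel=1e-12)
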