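"""Radial convection-diffusion-elimination solver verification.

Each numerical property is checked against an independent closed form:
the method-of-characteristics front for pure convection, the spherical
diffusion Green's function for the pump-off phase, the lumped mass
balance dM/dt = Q - k M during infusion, and exponential decay for
reaction-only dynamics.
"""

import numpy as np
import pytest

from cedsim.errors import DomainTooSmallError, ParameterError
from cedsim.metrics import crossing_radius
from cedsim.solver import (
    ConcentrationProfile,
    InfusionProtocol,
    SolverSettings,
    TissueModel,
    radial_velocity,
    solve_infusion,
    solve_post_infusion,
)
from cedsim.transport import Molecule

# a species with vanishing diffusivity isolates the advection scheme
CONVECTIVE_TRACER = Molecule("convective-tracer", 30400.0, 1e-30, 1.0)


def convection_front_radius(protocol: InfusionProtocol, porosity: float) -> float:
    """Method-of-characteristics front: infused volume fills phi * sphere shell."""
    return (
        protocol.source_radius**3
        + 3.0 * protocol.infusion_volume / (4.0 * np.pi * porosity)
    ) ** (1.0 / 3.0)


def shell_green_function(r, t, a, d):
    """Free-space diffusion of a unit spherical shell source at radius a."""
    return (
        1.0
        / (4.0 * np.pi * a * r * 2.0 * np.sqrt(np.pi * d * t))
        * (np.exp(-((r - a) ** 2) / (4 * d * t)) - np.exp(-((r + a) ** 2) / (4 * d * t)))
    )


class TestRadialVelocity:
    def test_reference_value(self, tissue, protocol_5):
        # Q/(4 pi phi r^2) at the source sphere
        v = radial_velocity(0.2, protocol_5, tissue)
        assert v == pytest.approx(5.53e-4, rel=2e-3)

    def test_inverse_square_falloff(self, tissue, protocol_5):
        assert radial_velocity(0.4, protocol_5, tissue) == pytest.approx(
            radial_velocity(0.2, protocol_5, tissue) / 4.0, rel=1e-12
        )

    @pytest.mark.parametrize("r", [0.2, 0.4, 0.8])
    def test_continuity_relation(self, r, tissue, protocol_5):
        flux = 4.0 * np.pi * r**2 * tissue.porosity * radial_velocity(r, protocol_5, tissue)
        assert flux == pytest.approx(protocol_5.rate_cgs, rel=1e-12)

    def test_inside_source_sphere_rejected(self, tissue, protocol_5):
        with pytest.raises(ParameterError):
            radial_velocity(0.1, protocol_5, tissue)


class TestInfusionPhase:
    def test_pure_convection_front_position(self, protocol_5, tissue_no_elim):
        profile = solve_infusion(protocol_5, tissue_no_elim, CONVECTIVE_TRACER)
        dr = profile.radii[1] - profile.radii[0]
        expected = convection_front_radius(protocol_5, tissue_no_elim.porosity)
        assert expected == pytest.approx(0.451, abs=5e-4)
        assert crossing_radius(profile, 0.5) == pytest.approx(expected, abs=dr)

    def test_mass_conservation_without_elimination(self, profile_5_no_elim, tissue_no_elim):
        held = profile_5_no_elim.total_solute_volume(tissue_no_elim.porosity)
        assert held == pytest.approx(0.105, rel=1e-2)

    def test_mass_balance_with_elimination(self, rate_comparison, tissue):
        # lumped balance: M(T) = (Q/k)(1 - e^{-kT}) in infusate-volume units
        profile = rate_comparison.profiles[5.0]
        protocol = profile.meta["protocol"]
        k = tissue.elimination_rate / 3600.0
        t_end = protocol.duration_h * 3600.0
        expected = protocol.rate_cgs / k * (1.0 - np.exp(-k * t_end))
        held = profile.total_solute_volume(tissue.porosity)
        assert held == pytest.approx(expected, rel=1e-2)

    def test_front_is_monotone_no_oscillations(self, rate_comparison):
        for rate, profile in rate_comparison.profiles.items():
            c = profile.values[-1]
            assert np.all(np.diff(c) <= 1e-12), f"oscillation at rate {rate}"
            assert c.min() >= -1e-12
            assert c.max() <= 1.0 + 1e-9

    def test_grid_convergence_of_crossing_radius(self, protocol_5, tissue, gdnf):
        r_vals = []
        for refine in (0.5, 1.0):
            profile = solve_infusion(
                protocol_5, tissue, gdnf, SolverSettings(refine=refine)
            )
            r_vals.append(crossing_radius(profile, 0.5))
        assert abs(r_vals[1] - r_vals[0]) / r_vals[1] < 0.005

    def test_front_reaching_outer_edge_raises(self, protocol_5, tissue, gdnf):
        with pytest.raises(DomainTooSmallError):
            solve_infusion(protocol_5, tissue, gdnf, SolverSettings(n_cells=64, r_max=0.4))


class TestPostInfusionPhase:
    def test_uniform_field_decays_exponentially(self):
        radii = np.linspace(0.21, 2.99, 600)
        initial = ConcentrationProfile(
            radii=radii, times=[0.0], values=0.5 * np.ones((1, radii.size))
        )
        out = solve_post_infusion(
            initial,
            TissueModel(elimination_rate=3.72e-2),
            CONVECTIVE_TRACER,
            duration_h=5.0,
            include_elimination=True,
        )
        expected = 0.5 * np.exp(-3.72e-2 * 5.0)
        np.testing.assert_allclose(out.values[-1], expected, rtol=1e-4)

    def test_matches_spherical_shell_greens_function(self, tissue_no_elim, gdnf):
        d = gdnf.effective_diffusivity
        a = 0.8
        t1, t2 = 0.25 * 3600.0, 0.75 * 3600.0
        faces = np.linspace(0.2, 3.0, 1201)
        centers = 0.5 * (faces[:-1] + faces[1:])
        c1 = shell_green_function(centers, t1, a, d)
        scale = c1.max()
        initial = ConcentrationProfile(
            radii=centers, times=[0.0], values=(c1 / scale)[None, :]
        )
        out = solve_post_infusion(initial, tissue_no_elim, gdnf, duration_h=0.5)
        exact = shell_green_function(centers, t2, a, d) / scale
        l2 = np.sqrt(
            np.sum((out.values[-1] - exact) ** 2 * centers**2)
            / np.sum(exact**2 * centers**2)
        )
        assert l2 < 0.01

    def test_tracer_spreads_farther_than_drug(
        self, profile_5_no_elim, tissue_no_elim, gdnf, gd_dtpa
    ):
        drug = solve_post_infusion(profile_5_no_elim, tissue_no_elim, gdnf, 2.0)
        tracer = solve_post_infusion(profile_5_no_elim, tissue_no_elim, gd_dtpa, 2.0)
        assert crossing_radius(tracer, 0.1) > crossing_radius(drug, 0.1)

    def test_mass_conserved_with_pump_off(self, profile_5_no_elim, tissue_no_elim, gdnf):
        out = solve_post_infusion(profile_5_no_elim, tissue_no_elim, gdnf, 2.0)
        before = profile_5_no_elim.total_solute_volume(tissue_no_elim.porosity)
        after = out.total_solute_volume(tissue_no_elim.porosity)
        assert after == pytest.approx(before, rel=1e-6)


class TestProfileContainer:
    def test_tidy_frame_round_trip(self, profile_5_no_elim, tmp_path):
        path = tmp_path / "profile.csv"
        profile_5_no_elim.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert set(frame.columns) == {"time_h", "radius_cm", "c_norm", "phase"}
        assert frame["radius_cm"].nunique() == profile_5_no_elim.radii.size

    def test_at_time_rejects_missing_time(self, profile_5_no_elim):
        with pytest.raises(ParameterError):
            profile_5_no_elim.at_time(123.456)

    def test_shape_validation(self):
        with pytest.raises(ParameterError):
            ConcentrationProfile(
                radii=[0.2, 0.3], times=[0.0], values=np.ones((1, 3))
            )
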