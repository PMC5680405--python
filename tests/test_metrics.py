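"""Distribution metrics: Peclet, crossing radii, Vd, homogeneity."""

import numpy as np
import pytest

from cedsim.errors import ParameterError
from cedsim.metrics import (
    crossing_radius,
    homogeneity_ratio,
    peclet,
    summarize_distribution,
    vd_from_radius,
)
from cedsim.solver import ConcentrationProfile
from cedsim.synthetic import generate_square_profile


def bisection_crossing_oracle(radii, values, threshold, tol=1e-12):
    """Outermost threshold crossing by bisection on the linear interpolant."""
    interp = lambda r: np.interp(r, radii, values)
    # locate the outermost bracketing cell by scanning from the outside
    for j in range(radii.size - 2, -1, -1):
        if values[j] >= threshold > values[j + 1]:
            lo, hi = radii[j], radii[j + 1]
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if interp(mid) >= threshold:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)
    return None


class TestPeclet:
    @pytest.mark.parametrize(
        "rate, radius, printed, digits",
        [
            (0.1, 0.467, 3.5, 1),
            (1.0, 0.553, 30, 0),
            (3.0, 0.558, 88, 0),
            (5.0, 0.558, 147, 0),
        ],
    )
    def test_reference_peclet_values(self, rate, radius, printed, digits, gdnf, tissue):
        assert round(peclet(rate, radius, gdnf, tissue), digits) == printed

    def test_inverse_linear_in_radius(self, gdnf, tissue):
        assert peclet(5.0, 0.8, gdnf, tissue) == pytest.approx(
            peclet(5.0, 0.4, gdnf, tissue) / 2.0, rel=1e-12
        )

    def test_positive_radius_required(self, gdnf, tissue):
        with pytest.raises(ParameterError):
            peclet(5.0, 0.0, gdnf, tissue)


class TestCrossingRadius:
    def test_square_profile(self):
        profile = generate_square_profile(0.45)
        dr = profile.radii[1] - profile.radii[0]
        assert crossing_radius(profile, 0.5) == pytest.approx(0.45, abs=dr / 2)

    def test_agrees_with_bisection_oracle(self, rate_comparison):
        profile = rate_comparison.profiles[5.0]
        got = crossing_radius(profile, 0.5)
        oracle = bisection_crossing_oracle(profile.radii, profile.values[-1], 0.5)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_threshold_one_on_subunity_profile_has_no_crossing(self, rate_comparison):
        profile = rate_comparison.profiles[1.0]
        assert crossing_radius(profile, 1.0) is None

    def test_everywhere_below_threshold_returns_none(self):
        radii = np.linspace(0.2, 1.0, 50)
        profile = ConcentrationProfile(
            radii=radii, times=[0.0], values=np.full((1, 50), 0.01)
        )
        assert crossing_radius(profile, 0.5) is None

    def test_outermost_crossing_wins_on_nonmonotone_profile(self):
        radii = np.linspace(0.2, 1.2, 101)
        values = np.where(radii < 0.5, 1.0, np.where(radii < 0.7, 0.2, 0.0))
        values[(radii >= 0.8) & (radii < 0.9)] = 0.6  # detached outer blob
        profile = ConcentrationProfile(radii=radii, times=[0.0], values=values[None, :])
        assert crossing_radius(profile, 0.5) > 0.8


class TestVolumes:
    @pytest.mark.parametrize(
        "radius, vd, tol",
        [(0.4924, 0.50, 0.005), (0.0, 0.0, 1e-12), (0.578, 0.81, 0.005)],
    )
    def test_sphere_volume(self, radius, vd, tol):
        assert vd_from_radius(radius) == pytest.approx(vd, abs=tol)

    def test_square_profile_volume_matches_quadrature(self):
        profile = generate_square_profile(0.45)
        r = crossing_radius(profile, 0.5)
        # quadrature oracle: integrate the super-threshold indicator,
        # plus the core sphere inside the grid's inner radius (C = 1 there)
        c = profile.values[0]
        dr = profile.radii[1] - profile.radii[0]
        core = (4.0 / 3.0) * np.pi * (profile.radii[0] - dr / 2.0) ** 3
        quad = core + np.sum(4.0 * np.pi * profile.radii[c >= 0.5] ** 2 * dr)
        assert vd_from_radius(r) == pytest.approx(quad, rel=0.01)


class TestHomogeneity:
    def test_square_profile_is_fully_homogeneous(self):
        profile = generate_square_profile(0.45)
        # ratio is slightly below 1 from the one-cell front ramp
        vd_high, vd_total, ratio = homogeneity_ratio(profile)
        assert ratio == pytest.approx(1.0, abs=0.03)
        assert vd_high <= vd_total

    def test_profile_without_plateau_scores_zero(self):
        # pure diffusion from a point-like source never nears C0
        radii = np.linspace(0.2, 2.0, 200)
        values = 0.5 * np.exp(-((radii - 0.2) ** 2) / 0.1)
        profile = ConcentrationProfile(radii=radii, times=[0.0], values=values[None, :])
        vd_high, _, ratio = homogeneity_ratio(profile)
        assert vd_high == 0.0
        assert ratio == 0.0

    def test_slow_infusion_far_less_homogeneous_than_fast(self, rate_comparison):
        table = rate_comparison.table.set_index("rate_ul_min")
        assert (
            table.loc[0.1, "homogeneity_ratio"]
            < table.loc[5.0, "homogeneity_ratio"] / 3.0
        )


def test_distribution_summary(rate_comparison, gdnf, tissue):
    profile = rate_comparison.profiles[5.0]
    protocol = profile.meta["protocol"]
    s = summarize_distribution(profile, protocol, tissue, gdnf)
    assert s.vd_high <= s.vd_total
    assert 0.0 <= s.homogeneity_ratio <= 1.0
    assert s.peclet_min == pytest.approx(peclet(5.0, s.r_half, gdnf, tissue), rel=1e-12)
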