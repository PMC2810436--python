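"""Analytic equilibrium predictions: oracles, limits, and invariants."""
import math

import numpy as np
import pytest

from neutralsar import (
    beta_diversity_F,
    dphi_dh,
    expected_density,
    g_function,
    linear_phase_sar,
    local_slope,
    make_params,
    phase_report,
    power_law_exponent,
    sar_closed_form,
    sar_exact,
    theta_s_from_density,
)


def g_function_mp(R, alpha, sigma, dps=50):
    """Independent arbitrary-precision evaluation of the Bessel combination."""
    import mpmath as mp

    with mp.workdps(dps):
        R, alpha, sigma = mp.mpf(R), mp.mpf(alpha), mp.mpf(sigma)
        kappa = mp.sqrt(alpha) / sigma
        x = kappa * R
        val = (R * mp.besselk(0, x) / mp.besselk(1, x) / (2 * sigma**2 * kappa)
               + R**2 / (8 * sigma**2))
        return float(val)


class TestGFunction:
    @pytest.mark.parametrize("scaled_arg", [0.01, 0.5, 2.0, 20.0])
    @pytest.mark.parametrize("alpha,sigma", [(0.05, 1.0), (0.01, 2.5)])
    def test_matches_high_precision_oracle(self, scaled_arg, alpha, sigma):
        R = scaled_arg * sigma / math.sqrt(alpha)
        assert g_function(R, alpha, sigma) == pytest.approx(
            g_function_mp(R, alpha, sigma), rel=1e-12
        )

    def test_large_argument_no_overflow(self):
        # R sqrt(alpha)/sigma = 700 would overflow unscaled Bessels
        val = g_function(700.0 / math.sqrt(0.04), 0.04, 1.0)
        assert np.isfinite(val) and val > 0

    def test_zero_radius_limit(self):
        assert g_function(0.0, 0.1, 1.0) == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            g_function(1.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            g_function(-1.0, 0.1, 1.0)


class TestSpeciesAreaCurves:
    def test_empty_region_holds_no_species(self):
        p = make_params(0.05, 1.0, 1.0)
        assert sar_closed_form(p, [0.0]).species[0] == 0.0
        assert sar_exact(p, [0.0]).species[0] == 0.0

    def test_strictly_increasing(self):
        p = make_params(0.02, 1.0, 0.5)
        S = sar_closed_form(p, np.geomspace(0.01, 500, 40)).species
        assert np.all(np.diff(S) > 0)

    def test_unsorted_radii_rejected(self):
        p = make_params(0.05, 1.0, 1.0)
        with pytest.raises(ValueError):
            sar_closed_form(p, [2.0, 1.0])

    def test_bounded_by_mean_abundance_at_large_radius(self):
        # beyond the correlation length the solution respects S <= rho * A
        p = make_params(0.05, 1.0, 0.25)
        R = np.array([10.0, 20.0, 50.0])
        S = sar_closed_form(p, R).species
        assert np.all(S < expected_density(p) * math.pi * R**2)

    def test_quadrature_matches_closed_form_through_power_law_phase(self):
        # the alpha_h expansion is near-exact through the sampling phase and
        # the first half (log scale) of the power-law window
        for alpha in (0.01, 0.05, 0.1):
            p = make_params(alpha, 1.0, 1.0)
            R = np.geomspace(0.05, alpha ** -0.25 / 2.5, 12)
            q = sar_exact(p, R).species
            c = sar_closed_form(p, R).species
            assert np.max(np.abs(c / q - 1.0)) < 0.01

    def test_quadrature_closed_form_transition_discrepancy_bounded(self):
        # around the power-law -> linear transition the expansion is a few
        # percent off the full integral; both converge again asymptotically
        p = make_params(0.05, 1.0, 1.0)
        R = np.geomspace(1.0 / math.sqrt(0.05), 300.0, 12)
        q = sar_exact(p, R).species
        c = sar_closed_form(p, R).species
        assert np.max(np.abs(c / q - 1.0)) < 0.12

    def test_mean_abundance_identity_at_h_zero(self):
        # dPhi/dh at h=0 equals the expected count in the window: the
        # normalization anchoring the h-quadrature (sum of probabilities = 1)
        p = make_params(0.1, 1.3, 0.8)
        for R in (0.5, 3.0, 20.0):
            assert dphi_dh(0.0, R, p) == pytest.approx(
                expected_density(p) * math.pi * R * R, rel=1e-13
            )


class TestLocalSlope:
    def test_sampling_phase_nearly_linear(self):
        p = make_params(0.01, 1.0, 1.0)
        s4 = local_slope(p, math.sqrt(1e-4 / math.pi))
        s8 = local_slope(p, math.sqrt(1e-8 / math.pi))
        assert 0.85 < s4 < 1.0
        assert s4 < s8 <= 1.0  # approaches 1 as the window shrinks

    def test_linear_phase_slope_is_one(self):
        p = make_params(0.01, 1.0, 1.0)
        A = 1e4 / 0.01
        assert abs(local_slope(p, math.sqrt(A / math.pi)) - 1.0) < 0.01

    def test_matches_exponent_at_evaluation_radius(self):
        alpha = 1e-4
        p = make_params(alpha, 1.0, 1.0)
        R_eval = alpha ** -0.25
        assert abs(local_slope(p, R_eval) - power_law_exponent(alpha)) < 0.01


class TestPowerLawExponent:
    def test_tropical_forest_value(self):
        assert round(power_law_exponent(1e-7), 2) == 0.21

    def test_increases_with_alpha(self):
        zs = [power_law_exponent(a) for a in np.geomspace(1e-10, 0.5, 25)]
        assert all(b > a for a, b in zip(zs, zs[1:]))
        assert all(0.0 < z < 1.0 for z in zs)

    def test_domain(self):
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                power_law_exponent(bad)


class TestLinearPhase:
    def test_exact_linearity(self):
        p = make_params(0.1, 1.0, 2.0)
        S = linear_phase_sar(p, [1.0, math.sqrt(2.0)]).species
        assert S[1] == pytest.approx(2.0 * S[0], rel=1e-14)

    def test_sigma_drops_out(self):
        a, t = 0.07, 1.3
        R = np.array([5.0, 50.0])
        s1 = linear_phase_sar(make_params(a, 1.0, t), R).species
        s2 = linear_phase_sar(make_params(a, 2.0, t), R).species
        np.testing.assert_allclose(s1, s2, rtol=1e-15)

    def test_asymptote_of_closed_form(self):
        p = make_params(0.05, 1.0, 1.0)
        A = 1e3 / 0.05
        R = [math.sqrt(A / math.pi)]
        lin = linear_phase_sar(p, R).species[0]
        closed = sar_closed_form(p, R).species[0]
        assert abs(closed / lin - 1.0) < 0.02


class TestDensity:
    def test_direct_substitution(self):
        assert expected_density(make_params(0.1, 1.0, 10.0)) == pytest.approx(100.0)
        assert expected_density(make_params(0.37, 1.0, 0.37)) == pytest.approx(1.0)

    def test_inversion_round_trip(self):
        p = make_params(0.034, 1.0, 0.81)
        assert theta_s_from_density(expected_density(p), p.alpha) == pytest.approx(
            p.theta_s, rel=1e-12
        )


class TestBetaDiversity:
    def test_strictly_decreasing(self):
        p = make_params(0.05, 1.0, 0.5)
        F = beta_diversity_F(p, np.geomspace(0.5, 20, 15)).F
        assert np.all(np.diff(F) < 0)

    def test_exponential_tail(self):
        # beyond the correlation length sigma/sqrt(alpha), F decays
        # exponentially: doubling r from 2 correlation lengths drops F by > e
        p = make_params(0.05, 1.0, 0.5)
        rstar = 2.0 * p.correlation_length
        F = beta_diversity_F(p, [rstar, 2.0 * rstar]).F
        assert F[1] / F[0] < math.exp(-1.0)

    def test_probability_domain_guard(self):
        # tiny theta_s pushes K0/(2 pi sigma^2 theta_s/alpha) above 1 at short r
        p = make_params(0.5, 1.0, 1e-4)
        with pytest.raises(ValueError, match="outside the validity"):
            beta_diversity_F(p, [0.01, 0.02, 0.05])

    def test_r_zero_rejected(self):
        p = make_params(0.05, 1.0, 0.5)
        with pytest.raises(ValueError):
            beta_diversity_F(p, [0.0, 1.0])


class TestPhaseReport:
    def test_direct_formulas(self):
        pr = phase_report(make_params(0.01, 1.0, 1.0))
        assert pr.A_small == pytest.approx(1.0)
        assert pr.A_large == pytest.approx(100.0)
        assert pr.R_eval == pytest.approx(math.sqrt(10.0))
        pr2 = phase_report(make_params(0.01, 2.0, 1.0))
        assert (pr2.A_small, pr2.A_large) == (pytest.approx(4.0), pytest.approx(400.0))

    def test_window_grows_as_inverse_alpha(self):
        r1 = phase_report(make_params(0.01, 1.0, 1.0))
        r2 = phase_report(make_params(0.001, 1.0, 1.0))
        assert r2.A_large / r2.A_small == pytest.approx(10.0 * r1.A_large / r1.A_small)

    def test_plateau_minimum_inside_window(self):
        p = make_params(0.01, 1.0, 1.0)
        pr = phase_report(p)
        A = np.geomspace(1e-3, 1e6, 80)
        slopes = [local_slope(p, math.sqrt(a / math.pi)) for a in A]
        A_min = A[int(np.argmin(slopes))]
        assert pr.A_small <= A_min <= pr.A_large
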