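"""First-order oscillatory solution, steady streaming profile, closed-form limits."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ciliaflow import (
    G_constants,
    critical_beta,
    field_from_groups,
    first_order_coefficients,
    first_order_velocity,
    gamma_n,
    parabola_coefficients,
    steady_constant_C,
    steady_profile,
    steady_solution,
    total_velocity,
    wall_velocity_closed_form,
)


def eq42_residuals(fo):
    """Residuals of the two wall Robin conditions for the mode-1 coefficients."""
    k, g1, phi = fo.k, fo.gamma1, fo.phi
    A1, B1 = fo.A1, fo.B1
    r1 = -k * A1 - g1 * B1 - phi * (k * k * A1 + g1 * g1 * B1) - 1.0 / 2.0j
    r2 = 1j * k * (A1 + B1 - phi * (-k * A1 - g1 * B1)) + fo.beta / 2.0
    return abs(r1), abs(r2)


class TestGamma:
    def test_stokes_limit_is_real(self):
        assert gamma_n(1, 10.0, 0.0) == pytest.approx(10.0 + 0.0j)

    def test_conjugate_mode(self):
        g1 = gamma_n(1, 31.4, 0.4)
        assert gamma_n(-1, 31.4, 0.4) == pytest.approx(g1.conjugate())

    def test_square_recovers_defining_quadratic(self):
        g1 = gamma_n(1, 31.4, 0.4)
        assert g1 * g1 == pytest.approx(complex(31.4**2, 0.4**2), rel=1e-14)
        assert g1.real >= 31.4

    def test_mode_zero_rejected(self):
        with pytest.raises(ValueError):
            gamma_n(0, 10.0, 0.4)


class TestFirstOrderCoefficients:
    @given(
        k=st.floats(1.0, 50.0),
        alpha=st.floats(0.05, 2.0),
        beta=st.floats(-2.0, 3.0),
        phi=st.floats(0.0, 5.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_boundary_system_satisfied(self, k, alpha, beta, phi):
        fo = first_order_coefficients(k, alpha, beta, phi)
        r1, r2 = eq42_residuals(fo)
        # tolerance scaled by the largest term entering the residual: the
        # coefficients blow up as (gamma1 - k)^-1 when alpha -> 0 and the
        # system becomes ill-conditioned
        scale = max(1.0, k * k * (1.0 + phi * k) * max(abs(fo.A1), abs(fo.B1)))
        assert r1 < 1e-12 * scale and r2 < 1e-12 * scale

    def test_matches_dense_linear_solve(self):
        k, alpha, beta, phi = 31.4, 0.4, 0.5, 0.0
        fo = first_order_coefficients(k, alpha, beta, phi)
        g1 = fo.gamma1
        m = np.array(
            [
                [-k - phi * k * k, -g1 - phi * g1 * g1],
                [1j * k * (1 + phi * k), 1j * k * (1 + phi * g1)],
            ]
        )
        rhs = np.array([1.0 / 2.0j, -beta / 2.0])
        A1, B1 = np.linalg.solve(m, rhs)
        assert fo.A1 == pytest.approx(A1, rel=1e-10)
        assert fo.B1 == pytest.approx(B1, rel=1e-10)

    def test_stokes_limit_uses_repeated_root_basis(self):
        fo = first_order_coefficients(10.0, 0.0, 0.5, 0.3)
        assert fo.degenerate
        # boundary conditions in the (A + B y) e^{-ky} basis
        a0, da0, d2a0 = fo.a1(0.0), fo.da1(0.0), fo.d2a1(0.0)
        assert a0 - fo.phi * da0 == pytest.approx(0.5j * fo.beta / fo.k, abs=1e-13)
        assert da0 - fo.phi * d2a0 == pytest.approx(-0.5j, abs=1e-13)

    def test_alpha_to_zero_is_continuous(self):
        lim = first_order_coefficients(10.0, 0.0, 0.5, 0.3)
        near = first_order_coefficients(10.0, 1e-4, 0.5, 0.3)
        y = np.linspace(0.0, 1.0, 50)
        np.testing.assert_allclose(near.a1(y), lim.a1(y), atol=1e-8)


class TestFirstOrderVelocity:
    @pytest.mark.parametrize("theta", [0.0, 0.7, 2.5, 4.4])
    def test_no_slip_wall_velocity(self, theta):
        fo = first_order_coefficients(31.4, 0.4, 0.5, 0.0)
        u1, v1 = first_order_velocity(theta / fo.k, 0.0, 0.0, fo)
        assert u1 == pytest.approx(math.sin(theta), abs=1e-12)
        assert v1 == pytest.approx(0.5 * math.cos(theta), abs=1e-12)

    def test_robin_wall_condition_with_slip(self):
        fo = first_order_coefficients(20.0, 0.4, 0.8, 0.4)
        theta = 1.234
        x = theta / fo.k
        u1, v1 = first_order_velocity(x, 0.0, 0.0, fo)
        du = 2.0 * np.real(fo.d2a1(0.0) * cmath.exp(1j * theta))
        dv = 2.0 * fo.k * np.imag(fo.da1(0.0) * cmath.exp(1j * theta))
        assert u1 - fo.phi * du == pytest.approx(math.sin(theta), abs=1e-12)
        assert v1 - fo.phi * dv == pytest.approx(fo.beta * math.cos(theta), abs=1e-12)

    def test_exponential_decay_bound_at_top(self):
        fo = first_order_coefficients(12.0, 0.4, 0.5, 0.0)
        t = np.linspace(0.0, 2.0 * math.pi, 40)
        u1, v1 = first_order_velocity(0.3, 1.0, t, fo)
        assert np.max(np.abs(u1)) < math.exp(-12.0) * 1e3
        assert np.max(np.abs(v1)) < math.exp(-12.0) * 1e3

    def test_amplitude_ode_residual_by_finite_differences(self):
        """a1'''' - (2k^2+i a^2) a1'' + (k^4+i k^2 a^2) a1 = 0, checked with
        4th-order stencils at random interior points."""
        fo = first_order_coefficients(10.0, 0.4, 0.5, 0.1)
        k, al = fo.k, fo.alpha
        h = 3e-3
        rng = np.random.default_rng(7)
        for y in rng.uniform(0.05, 0.6, 8):
            ys = y + h * np.arange(-3, 4)
            a = fo.a1(ys)
            d4 = (-a[0] / 6 + 2 * a[1] - 13 * a[2] / 2 + 28 * a[3] / 3
                  - 13 * a[4] / 2 + 2 * a[5] - a[6] / 6) / h**4
            d2 = (-a[1] / 12 + 4 * a[2] / 3 - 5 * a[3] / 2 + 4 * a[4] / 3 - a[5] / 12) / h**2
            res = d4 - (2 * k * k + 1j * al * al) * d2 + (k**4 + 1j * k * k * al * al) * a[3]
            # normalise by the envelope of the two exponential modes: a1
            # itself is their near-cancelling difference, while the stencil's
            # h^4 truncation error scales with the modes individually
            envelope = abs(fo.A1) * np.exp(-k * ys[3]) + abs(fo.B1) * np.exp(
                -fo.gamma1.real * ys[3]
            )
            assert abs(res) / (k**4 * envelope) < 1e-5


class TestSteadyConstants:
    def test_C_vanishes_for_flat_beating(self):
        assert steady_constant_C(0.0, 31.4, gamma_n(1, 31.4, 0.4)) == 0.0

    def test_C_equals_k_for_circular_tips(self):
        k = 17.0
        assert steady_constant_C(1.0, k, gamma_n(1, k, 0.4)) == pytest.approx(k)

    @given(
        k=st.floats(2.0, 50.0),
        alpha=st.floats(0.05, 2.0),
        beta=st.floats(-2.0, 3.0),
        phi=st.floats(0.0, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_C_closed_form_matches_first_order_shear_average(self, k, alpha, beta, phi):
        fo = first_order_coefficients(k, alpha, beta, phi)
        C_closed = steady_constant_C(beta, k, fo.gamma1)
        C_direct = 2.0 * beta * np.imag(
            fo.d2a1(0.0) - phi * (-fo.k**3 * fo.A1 - fo.gamma1**3 * fo.B1)
        )
        scale = max(1.0, k**3 * (1.0 + phi) * max(abs(fo.A1), abs(fo.B1)))
        assert abs(C_closed - C_direct) < 1e-12 * scale

    def test_G_constants_stokes_limit(self):
        fo = first_order_coefficients(10.0, 0.0, 0.5, 0.2)
        C = steady_constant_C(0.5, 10.0, fo.gamma1)
        assert G_constants(fo, C) == (0.0, 0.0, -10.0 - C)

    def test_G1_G2_negligible_at_large_k(self):
        for k in (10.0, 20.0, 40.0):
            for alpha in (0.2, 0.4, 1.0):
                fo = first_order_coefficients(k, alpha, 0.5, 0.1)
                C = steady_constant_C(0.5, k, fo.gamma1)
                G1, G2, G3 = G_constants(fo, C)
                assert abs(G1) < 1e-3 * abs(G3)
                assert abs(G2) < 1e-3 * abs(G3)

    @given(
        k=st.floats(2.0, 50.0),
        alpha=st.floats(0.01, 1.5),
        beta=st.floats(-1.5, 2.5),
        phi=st.floats(0.0, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_parabola_coefficients_satisfy_all_three_conditions(self, k, alpha, beta, phi):
        fo = first_order_coefficients(k, alpha, beta, phi)
        ss = steady_solution(fo)
        assert ss.A2 + ss.B2 + ss.C2 + ss.G1 == pytest.approx(0.0, abs=1e-9)
        assert 2.0 * ss.A2 + ss.B2 + ss.G2 == pytest.approx(0.0, abs=1e-9)
        assert ss.C2 - phi * ss.B2 + ss.G3 == pytest.approx(0.0, abs=1e-8)


class TestSteadyProfile:
    def test_stagnant_interface(self):
        fo = first_order_coefficients(15.0, 0.4, 0.5, 0.1)
        ss = steady_solution(fo)
        assert steady_profile(1.0, ss, fo) == pytest.approx(0.0, abs=1e-10)
        dy = 1e-6
        shear = (steady_profile(1.0, ss, fo) - steady_profile(1.0 - dy, ss, fo)) / dy
        assert shear == pytest.approx(0.0, abs=1e-4)

    def test_robin_condition_closes_the_system(self):
        fo = first_order_coefficients(12.0, 0.7, 0.8, 0.3)
        ss = steady_solution(fo)
        dy = 1e-4
        u0 = steady_profile(0.0, ss, fo)
        du0 = (
            -3.0 * steady_profile(0.0, ss, fo)
            + 4.0 * steady_profile(dy, ss, fo)
            - steady_profile(2.0 * dy, ss, fo)
        ) / (2.0 * dy)
        k_plus_C = fo.k + ss.Cconst
        assert u0 - fo.phi * du0 == pytest.approx(k_plus_C, rel=1e-6)

    @pytest.mark.parametrize("k", [10.0, 20.0, 40.0])
    @pytest.mark.parametrize("alpha", [0.1, 0.4, 1.0])
    def test_profile_is_parabolic_to_half_percent(self, k, alpha):
        fo = first_order_coefficients(k, alpha, 0.5, 0.0)
        ss = steady_solution(fo)
        y = np.linspace(0.0, 1.0, 101)
        full = steady_profile(y, ss, fo)
        parab = -ss.G3 / (1.0 + 2.0 * fo.phi) * (y - 1.0) ** 2
        assert np.max(np.abs(full - parab)) < 0.005 * abs(steady_profile(0.0, ss, fo))

    def test_exponential_terms_explain_wall_gap(self):
        fo = first_order_coefficients(10.0, 0.8, 0.5, 0.0)
        ss = steady_solution(fo)
        kg = fo.k + np.conj(fo.gamma1)
        gg = 2.0 * fo.gamma1.real
        expo0 = np.real(fo.A1 * np.conj(fo.B1) / kg**2) + abs(fo.B1) ** 2 / gg**2
        parab0 = ss.C2
        assert steady_profile(0.0, ss, fo) - parab0 == pytest.approx(
            -4.0 * fo.alpha**4 * fo.k * expo0, rel=1e-10
        )

    def test_converges_to_parabola_as_alpha_fourth(self):
        def gap(alpha):
            fo = first_order_coefficients(10.0, alpha, 0.5, 0.0)
            ss = steady_solution(fo)
            y = np.linspace(0.0, 1.0, 201)
            parab = -ss.G3 / (1.0 + 2.0 * fo.phi) * (y - 1.0) ** 2
            return np.max(np.abs(steady_profile(y, ss, fo) - parab))

        g1, g2 = gap(0.4), gap(0.2)
        assert g1 / g2 == pytest.approx(16.0, rel=0.5)


class TestClosedFormLimits:
    def test_flat_beating_value(self):
        assert wall_velocity_closed_form(0.1, 10.0, 0.0, 0.5) == pytest.approx(
            0.01 * 10.0 / (2.0 * 2.0)
        )

    def test_circular_tips_maximise_transport(self):
        eps, k, phi = 0.1, 10.0, 0.3
        betas = np.linspace(-3.0, 5.0, 1601)
        u = np.array([wall_velocity_closed_form(eps, k, b, phi) for b in betas])
        assert u.max() == pytest.approx(eps * eps * k / (1.0 + 2.0 * phi), rel=1e-6)
        assert betas[np.argmax(u)] == pytest.approx(1.0, abs=5e-3)

    def test_no_wave_no_transport(self):
        assert wall_velocity_closed_form(0.1, 0.0, 0.5, 0.0) == 0.0

    def test_zero_at_critical_eccentricity(self):
        bc = critical_beta()
        assert bc == pytest.approx(1.0 + math.sqrt(2.0), rel=1e-15)
        for eps, k, phi in [(0.1, 10.0, 0.0), (0.2, 31.4, 0.7)]:
            assert wall_velocity_closed_form(eps, k, bc, phi) == pytest.approx(0.0, abs=1e-13)

    def test_bisection_recovers_critical_eccentricity(self):
        root = brentq(
            lambda b: wall_velocity_closed_form(0.1, 10.0, b, 0.0), 1.0, 4.0,
            xtol=1e-12,
        )
        assert root == pytest.approx(critical_beta(), abs=1e-10)

    def test_monotone_decreasing_in_slip(self):
        phis = np.linspace(0.0, 5.0, 30)
        u = np.array([wall_velocity_closed_form(0.1, 10.0, 0.5, p) for p in phis])
        assert np.all(np.diff(u) < 0)

    def test_direction_set_by_wave_and_shape_factor_only(self):
        # reversing the wave reverses the flow; the sign of the flow is the
        # sign of (1 + 2 beta - beta^2) times the wave direction
        for beta in (-0.5, 0.0, 0.5, 1.0, 2.0, 3.0):
            shape = 1.0 + 2.0 * beta - beta * beta
            u = wall_velocity_closed_form(0.1, 10.0, beta, 0.2)
            assert math.copysign(1.0, u) == math.copysign(1.0, shape) or u == 0.0
            u_rev = -wall_velocity_closed_form(0.1, 10.0, beta, 0.2)  # mirrored x
            assert u_rev == -u


class TestTotalVelocity:
    def test_time_average_is_steady_part(self):
        field = field_from_groups(eps=0.16, k=31.4, alpha=0.4, beta=0.5, phi=0.1)
        t = np.arange(64) * 2.0 * math.pi / 64
        x, y = 0.13, 0.21
        u = np.array([total_velocity(x, y, ti, field)[0] for ti in t])
        steady = 0.5 * field.g.eps**2 * steady_profile(y, field.ss, field.fo)
        assert u.mean() == pytest.approx(float(steady), rel=1e-10)

    def test_periodic_in_x_and_t(self):
        field = field_from_groups(eps=0.1, k=12.0, alpha=0.4, beta=0.5, phi=0.0)
        u0, v0 = total_velocity(0.3, 0.15, 1.1, field)
        u1, v1 = total_velocity(0.3 + 2.0 * math.pi / 12.0, 0.15, 1.1, field)
        u2, v2 = total_velocity(0.3, 0.15, 1.1 + 2.0 * math.pi, field)
        assert u0 == pytest.approx(u1, rel=1e-10) and v0 == pytest.approx(v1, rel=1e-10)
        assert u0 == pytest.approx(u2, rel=1e-10) and v0 == pytest.approx(v2, rel=1e-10)

    def test_far_field_is_straight_steady_flow(self, reference_field):
        f = reference_field
        y = 0.5  # many wavelengths above the edge at k = 10 pi
        t = np.linspace(0.0, 2.0 * math.pi, 30)
        u, v = total_velocity(0.2, y, t, f)
        steady = float(f.steady_velocity(y))
        assert np.max(np.abs(u - steady)) < 1e-4 * steady
        assert np.max(np.abs(v)) < 1e-4 * steady
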