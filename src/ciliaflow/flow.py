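"""Analytic solution of the envelope-driven flow in the strip 0 <= y <= 1.

The stream function is expanded in powers of eps = a/h.  At first order the
flow is a purely oscillatory solution of the unsteady Stokes equation,
written as a single travelling Fourier mode with decaying vertical structure
``a1(y) = A1 e^{-ky} + B1 e^{-gamma1 y}``, gamma1 = sqrt(k^2 + i alpha^2).
At second order a steady streaming component appears whose horizontal
profile is a parabola in y plus two exponentially small corrections; it is
this steady part that transports micro-beads.

Conventions: theta = k x + t is the local wave phase; the metachronal wave
travels towards -x (antiplectic), and for small tip eccentricity beta the
steady flow is towards +x.  Growing exponentials in y are dropped, which is
exact in the limit e^{-k} -> 0; accuracy degrades for k below about 5.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .params import BeadParams, CiliaParams, DimensionlessGroups, FluidParams, dimensionless_groups

__all__ = [
    "FirstOrderSolution",
    "SteadySolution",
    "FlowField",
    "gamma_n",
    "first_order_coefficients",
    "first_order_velocity",
    "steady_constant_C",
    "G_constants",
    "parabola_coefficients",
    "steady_solution",
    "steady_profile",
    "wall_velocity_closed_form",
    "critical_beta",
    "total_velocity",
    "build_field",
    "field_from_groups",
]


def gamma_n(n: int, k: float, alpha: float) -> complex:
    """Decaying characteristic root sqrt(k^2 n^2 + i n alpha^2) of mode n.

    The principal square root is taken, so Re(gamma_n) >= k|n| and the
    retained vertical structure e^{-gamma_n y} decays away from the wall.
    Conjugate symmetry gamma_{-n} = conj(gamma_n) holds by construction.
    """
    if n == 0:
        raise ValueError("gamma_n is defined for non-zero mode index n")
    return cmath.sqrt(complex(k * k * n * n, n * alpha * alpha))


@dataclass(frozen=True)
class FirstOrderSolution:
    """Coefficients of the first-order (oscillatory) stream function.

    ``a1(y) = A1 e^{-ky} + B1 e^{-gamma1 y}`` in the generic case; when
    alpha = 0 the two roots coincide (gamma1 = k) and the repeated-root basis
    ``a1(y) = (A1 + B1 y) e^{-ky}`` is used instead (``degenerate=True``).
    """

    A1: complex
    B1: complex
    gamma1: complex
    k: float
    alpha: float
    beta: float
    phi: float
    degenerate: bool = False

    def a1(self, y):
        y = np.asarray(y, dtype=float)
        if self.degenerate:
            return (self.A1 + self.B1 * y) * np.exp(-self.k * y)
        return self.A1 * np.exp(-self.k * y) + self.B1 * np.exp(-self.gamma1 * y)

    def da1(self, y):
        y = np.asarray(y, dtype=float)
        if self.degenerate:
            return (self.B1 - self.k * (self.A1 + self.B1 * y)) * np.exp(-self.k * y)
        return -(
            self.k * self.A1 * np.exp(-self.k * y)
            + self.gamma1 * self.B1 * np.exp(-self.gamma1 * y)
        )

    def d2a1(self, y):
        y = np.asarray(y, dtype=float)
        if self.degenerate:
            k = self.k
            return (k * k * (self.A1 + self.B1 * y) - 2.0 * k * self.B1) * np.exp(-k * y)
        return (
            self.k**2 * self.A1 * np.exp(-self.k * y)
            + self.gamma1**2 * self.B1 * np.exp(-self.gamma1 * y)
        )


def first_order_coefficients(
    k: float, alpha: float, beta: float, phi: float
) -> FirstOrderSolution:
    """Solve the wall Robin conditions for the mode-1 coefficients (A1, B1).

    Closed form for alpha > 0::

        A1 = i/(2 (1 + k phi)) * (beta gamma1/k - 1) / (gamma1 - k)
        B1 = i/(2 (1 + gamma1 phi)) * (1 - beta) / (gamma1 - k)

    For alpha = 0 the system is singular in this basis (gamma1 = k); the
    repeated-root basis {e^{-ky}, y e^{-ky}} is solved instead, giving the
    exact steady-Stokes limit.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    g1 = gamma_n(1, k, alpha)
    if alpha == 0.0:
        # basis (A + B y) e^{-ky}: Robin pair at y=0 gives a 2x2 real-structured
        # system for (A, B)
        m = np.array(
            [
                [1.0 + k * phi, -phi],
                [-k * (1.0 + k * phi), 1.0 + 2.0 * k * phi],
            ],
            dtype=complex,
        )
        rhs = np.array([0.5j * beta / k, -0.5j], dtype=complex)
        A1, B1 = np.linalg.solve(m, rhs)
        return FirstOrderSolution(A1, B1, g1, k, alpha, beta, phi, degenerate=True)
    A1 = 0.5j * (beta * g1 / k - 1.0) / ((g1 - k) * (1.0 + k * phi))
    B1 = 0.5j * (1.0 - beta) / ((g1 - k) * (1.0 + g1 * phi))
    return FirstOrderSolution(A1, B1, g1, k, alpha, beta, phi)


def first_order_velocity(x, y, t, fo: FirstOrderSolution) -> Tuple[np.ndarray, np.ndarray]:
    """Oscillatory velocity (u1, v1) before the eps factor.

    u1 = 2 Re{a1'(y) e^{i theta}}, v1 = 2k Im{a1(y) e^{i theta}} with
    theta = k x + t.  At the wall (y=0, phi=0) this reproduces the envelope
    velocity (sin theta, beta cos theta) exactly.
    """
    theta = fo.k * np.asarray(x, dtype=float) + np.asarray(t, dtype=float)
    phase = np.exp(1j * theta)
    u1 = 2.0 * np.real(fo.da1(y) * phase)
    v1 = 2.0 * fo.k * np.imag(fo.a1(y) * phase)
    return u1, v1


def steady_constant_C(beta: float, k: float, gamma1: complex) -> float:
    """Steady wall-condition constant C = beta*k + beta*(1-beta)*Re(gamma1).

    C is the time-averaged contribution of the first-order shear, sampled by
    the oscillating wall, to the second-order Robin condition.
    """
    return beta * k + beta * (1.0 - beta) * gamma1.real


def G_constants(fo: FirstOrderSolution, C: float) -> Tuple[float, float, float]:
    """Boundary constants (G1, G2, G3) of the steady second-order profile.

    All three collect the exponential (streaming) part of the profile at the
    boundaries; G1 and G2 carry an extra factor e^{-(k+Re gamma1)} and are
    negligible against G3 in the experimental regime k >= 10.  At alpha = 0
    the streaming forcing vanishes identically and (G1, G2, G3) =
    (0, 0, -k - C).
    """
    k = fo.k
    if fo.degenerate or fo.alpha == 0.0:
        return 0.0, 0.0, -k - C
    s = 4.0 * fo.alpha**4 * k
    kg = k + np.conj(fo.gamma1)          # k + conj(gamma1)
    gg = 2.0 * fo.gamma1.real            # gamma1 + conj(gamma1)
    AB = fo.A1 * np.conj(fo.B1)
    B2sq = abs(fo.B1) ** 2
    e_kg = math.exp(-kg.real) * cmath.exp(-1j * kg.imag)
    e_gg = math.exp(-gg)
    G1 = s * (-np.real(AB * e_kg / kg**2) - B2sq * e_gg / gg**2)
    G2 = s * (np.real(AB * e_kg / kg) + B2sq * e_gg / gg)
    G3 = -(k + C) + s * (
        -np.real(AB / kg**2)
        - fo.phi * np.real(AB / kg)
        - B2sq / gg**2
        - fo.phi * B2sq / gg
    )
    return float(G1), float(G2), float(G3)


def parabola_coefficients(
    G1: float, G2: float, G3: float, phi: float
) -> Tuple[float, float, float]:
    """Coefficients (A2, B2, C2) of the steady parabola A2 y^2 + B2 y + C2.

    They enforce vanishing velocity and shear at y = 1 and the Robin
    condition at y = 0; A2 is also the steady horizontal pressure gradient.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    den = 1.0 + 2.0 * phi
    A2 = (G1 - (1.0 + phi) * G2 - G3) / den
    B2 = (-2.0 * G1 + G2 + 2.0 * G3) / den
    C2 = (-2.0 * phi * G1 + phi * G2 - G3) / den
    return A2, B2, C2


@dataclass(frozen=True)
class SteadySolution:
    """Second-order steady profile: parabola + exponential streaming tail."""

    Cconst: float
    G1: float
    G2: float
    G3: float
    A2: float
    B2: float
    C2: float

    @property
    def px_s(self) -> float:
        """Steady dimensionless pressure gradient along x (equals A2)."""
        return self.A2


def steady_solution(fo: FirstOrderSolution) -> SteadySolution:
    """Assemble the full steady second-order solution from the first order."""
    C = steady_constant_C(fo.beta, fo.k, fo.gamma1)
    G1, G2, G3 = G_constants(fo, C)
    A2, B2, C2 = parabola_coefficients(G1, G2, G3, fo.phi)
    return SteadySolution(C, G1, G2, G3, A2, B2, C2)


def steady_profile(y, ss: SteadySolution, fo: FirstOrderSolution):
    """Steady horizontal velocity u2s(y), before the eps^2/2 factor.

    Parabola A2 y^2 + B2 y + C2 minus the exponentially decaying streaming
    terms; satisfies u2s(1) = 0 and u2s'(1) = 0 by construction.
    """
    y = np.asarray(y, dtype=float)
    poly = ss.A2 * y * y + ss.B2 * y + ss.C2
    if fo.degenerate or fo.alpha == 0.0:
        return poly
    kg = fo.k + np.conj(fo.gamma1)
    gg = 2.0 * fo.gamma1.real
    expo = np.real(fo.A1 * np.conj(fo.B1) * np.exp(-kg * y) / kg**2) + (
        abs(fo.B1) ** 2
    ) * np.exp(-gg * y) / gg**2
    return poly - 4.0 * fo.alpha**4 * fo.k * expo


def wall_velocity_closed_form(eps: float, k: float, beta: float, phi: float) -> float:
    """Large-k, small-alpha steady slip velocity at the ciliated edge.

    ``u(0) = (eps^2/2) k (1 + 2 beta - beta^2) / (1 + 2 phi)``.  Positive
    (opposite to the wave) for beta below the critical eccentricity
    1 + sqrt(2), zero at k = 0 (no metachrony, no transport).
    """
    return 0.5 * eps * eps * k * (1.0 + 2.0 * beta - beta * beta) / (1.0 + 2.0 * phi)


def critical_beta() -> float:
    """Eccentricity 1 + sqrt(2) at which the steady flow reverses sign."""
    return 1.0 + math.sqrt(2.0)


@dataclass(frozen=True)
class FlowField:
    """Complete flow solution u = eps*u1 + (eps^2/2)*u2s, v = eps*v1.

    The second-order oscillatory (e^{+-2i theta}) component is not part of
    the model: only the steady second-order term is retained, since it alone
    survives time averaging and controls tracer transport.

    When built from physical parameters (see :func:`build_field`) the field
    also carries them, so downstream code can re-dimensionalise velocities
    by h*omega.
    """

    g: DimensionlessGroups
    beta: float
    fo: FirstOrderSolution
    ss: SteadySolution
    cilia: Optional[CiliaParams] = None
    fluid: Optional[FluidParams] = None

    def velocity(self, x, y, t) -> Tuple[np.ndarray, np.ndarray]:
        u1, v1 = first_order_velocity(x, y, t, self.fo)
        u2s = steady_profile(y, self.ss, self.fo)
        eps = self.g.eps
        return eps * u1 + 0.5 * eps * eps * u2s, eps * v1

    def steady_velocity(self, y):
        """Time-averaged horizontal velocity (eps^2/2) u2s(y)."""
        return 0.5 * self.g.eps**2 * steady_profile(y, self.ss, self.fo)

    @property
    def velocity_scale(self) -> float:
        """h*omega in um/s; requires physical parameters."""
        if self.cilia is None:
            raise ValueError("field was built without physical parameters")
        return self.cilia.h * self.cilia.omega


def total_velocity(x, y, t, field: FlowField) -> Tuple[np.ndarray, np.ndarray]:
    """Dimensionless total velocity (u, v) at (x, y, t)."""
    return field.velocity(x, y, t)


def build_field(
    cilia: CiliaParams,
    fluid: FluidParams,
    bead: Optional[BeadParams] = None,
) -> FlowField:
    """Construct the flow field for a physical parameter set."""
    g = dimensionless_groups(cilia, fluid, bead)
    fo = first_order_coefficients(g.k, g.alpha, cilia.beta, g.phi)
    return FlowField(g=g, beta=cilia.beta, fo=fo, ss=steady_solution(fo),
                     cilia=cilia, fluid=fluid)


def field_from_groups(eps: float, k: float, alpha: float, beta: float, phi: float,
                      stk: Optional[float] = None) -> FlowField:
    """Construct a flow field directly from dimensionless groups."""
    g = DimensionlessGroups(eps=eps, k=k, alpha=alpha, phi=phi, stk=stk)
    fo = first_order_coefficients(k, alpha, beta, phi)
    return FlowField(g=g, beta=beta, fo=fo, ss=steady_solution(fo))
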