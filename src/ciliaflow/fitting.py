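"""Parabolic fits of bead-velocity profiles and the beating efficiency index.

The model predicts a steady velocity profile V(y) = U0 (1 - y/h)^2 above the
ciliated edge, vanishing (with its shear) at the stagnation height h.  From
a fitted (U0, h) the wall shear stress

    tau_w = 2 mu U0 / h

is the proposed clinical index of beating efficiency, and the sliding length
phi* of the partial-slip wall condition can be inferred by inverting

    U0 = (pi a^2 omega / lam) (1 + 2 beta - beta^2) / (1 + 2 phi*/h).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .params import CP, CiliaParams

__all__ = [
    "VelocityProfile",
    "FitResult",
    "fit_parabola",
    "shear_index",
    "infer_phi",
    "predict_U0",
]


class FitError(RuntimeError):
    """Profile fit failed from every starting point."""


@dataclass
class VelocityProfile:
    """Sampled (distance to edge, effective speed) pairs.

    Physical profiles carry y in um and v in um/s; ``dimensionless=True``
    marks model-unit profiles (y in units of h, v in units of h*omega).
    """

    y: np.ndarray
    v: np.ndarray
    weights: Optional[np.ndarray] = None
    dimensionless: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.y.shape != self.v.shape:
            raise ValueError("y and v must have the same length")
        if np.any(self.y < 0):
            raise ValueError("distances to the edge must be >= 0")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.y.shape:
                raise ValueError("weights must match the sample length")

    def __len__(self) -> int:
        return self.y.size


@dataclass
class FitResult:
    """Fitted parabola and derived quantities.

    ``covariance`` is the 2x2 Jacobian-based uncertainty of (U0, h).
    ``null`` flags a degenerate all-zero profile for which no parabola is
    identifiable (U0 = 0, h undefined).
    """

    U0: float
    h_fit: float
    tau_w: Optional[float] = None
    phi_star_fit: Optional[float] = None
    covariance: Optional[np.ndarray] = None
    residual_norm: float = 0.0
    n_points: int = 0
    null: bool = False

    def predict(self, y):
        y = np.asarray(y, dtype=float)
        return self.U0 * np.clip(1.0 - y / self.h_fit, 0.0, None) ** 2


def _model(params, y):
    U0, h = params
    return U0 * np.clip(1.0 - y / h, 0.0, None) ** 2


def fit_parabola(
    profile: VelocityProfile,
    mu: Optional[float] = None,
    fix_h: Optional[float] = None,
) -> FitResult:
    """Nonlinear least-squares fit of V(y) = U0 max(0, 1 - y/h)^2.

    Points beyond the stagnation height are modelled as zero velocity, so
    samples with y > h do not destabilise the fit.  Because (U0, h) are
    strongly correlated when the data stop short of the stagnation region,
    the optimiser is multi-started from h in {1.2, 2, 4} x max(y); the best
    optimum is kept.

    Parameters
    ----------
    profile : VelocityProfile
        At least 4 samples at not-all-identical heights.
    mu : float, optional
        Fluid viscosity in cP; when given (and the profile is physical) the
        wall shear stress tau_w = 2 mu U0 / h is filled in, in Pa.
    fix_h : float, optional
        Constrain the stagnation height instead of fitting it.

    Raises
    ------
    FitError
        If no start converges.
    """
    if len(profile) < 4:
        raise ValueError(f"need at least 4 points to fit, got {len(profile)}")
    y, v = profile.y, profile.v
    if np.ptp(y) == 0:
        raise ValueError("all sample heights are identical; parabola is unidentifiable")

    vmax = float(np.max(np.abs(v)))
    if vmax < 1e-30:
        return FitResult(U0=0.0, h_fit=math.nan, tau_w=0.0 if mu is not None else None,
                         residual_norm=0.0, n_points=len(profile), null=True)

    w = np.ones_like(y) if profile.weights is None else np.sqrt(profile.weights)

    if fix_h is not None:
        # linear in U0 at fixed h
        basis = np.clip(1.0 - y / fix_h, 0.0, None) ** 2
        wb = w * basis
        U0 = float(np.dot(wb, w * v) / np.dot(wb, wb))
        res = w * (basis * U0 - v)
        return _finalize(U0, fix_h, res, None, profile, mu)

    U0_start = float(np.max(v))
    best = None
    for factor in (1.2, 2.0, 4.0):
        h_start = factor * float(np.max(y))
        try:
            sol = least_squares(
                lambda p: w * (_model(p, y) - v),
                x0=[U0_start, h_start],
                bounds=([0.0, 1e-12], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("parabola fit did not converge from any start")

    U0, h = best.x
    jac = best.jac
    cov = None
    dof = len(profile) - 2
    if dof > 0:
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * (2.0 * best.cost / dof)
        except np.linalg.LinAlgError:
            cov = None
    return _finalize(float(U0), float(h), best.fun, cov, profile, mu)


def _finalize(U0, h, residuals, cov, profile, mu) -> FitResult:
    tau = None
    if mu is not None and not profile.dimensionless:
        tau = shear_index(mu, U0, h)
    return FitResult(
        U0=U0, h_fit=h, tau_w=tau, covariance=cov,
        residual_norm=float(np.linalg.norm(residuals)), n_points=len(profile),
    )


def shear_index(mu: float, U0: float, h: float) -> float:
    """Wall shear stress tau_w = 2 mu U0 / h, in Pa.

    ``mu`` in cP, ``U0`` in um/s, ``h`` in um; the um in U0 and h cancel, so
    only the viscosity needs conversion to SI.
    """
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    return 2.0 * (mu * CP) * U0 / h


def predict_U0(c: CiliaParams, beta: Optional[float] = None) -> float:
    """Model wall velocity U0 = (pi a^2 omega/lam)(1+2b-b^2)/(1+2 phi*/h), um/s."""
    b = c.beta if beta is None else beta
    return (
        math.pi * c.a**2 * c.omega / c.lam
        * (1.0 + 2.0 * b - b * b)
        / (1.0 + 2.0 * c.phi_star / c.h)
    )


def infer_phi(U0: float, c: CiliaParams, beta: float = 0.0) -> float:
    """Invert the wall-velocity formula for the sliding length phi*, in um.

    ``beta`` defaults to 0 (flat beating approximation).  A measured U0
    larger than the no-slip (phi*=0) prediction has no physical solution;
    the result is then clipped to 0 with a warning.
    """
    if U0 <= 0:
        raise ValueError(f"U0 must be positive to infer phi*, got {U0}")
    shape = 1.0 + 2.0 * beta - beta * beta
    if shape <= 0:
        raise ValueError(
            f"1 + 2*beta - beta^2 = {shape:.3g} <= 0 at beta={beta}: no "
            "sliding length phi* >= 0 can produce a positive U0"
        )
    phi_star = 0.5 * c.h * (math.pi * c.a**2 * c.omega * shape / (c.lam * U0) - 1.0)
    if -1e-9 * c.h < phi_star < 0:  # roundoff at the no-slip boundary
        return 0.0
    if phi_star < 0:
        warnings.warn(
            f"measured U0={U0:.3g} um/s exceeds the no-slip prediction "
            f"{math.pi * c.a**2 * c.omega * shape / c.lam:.3g} um/s; "
            "clipping phi* to 0",
            stacklevel=2,
        )
        return 0.0
    return phi_star
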