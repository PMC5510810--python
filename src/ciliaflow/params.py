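"""Physical parameter containers and the dimensionless groups derived from them.

All user-facing quantities are expressed in the units used at the bench:
lengths in micrometres, frequencies in hertz, densities in g/cm^3 and
viscosities in centipoise.  Conversion to SI happens internally, only where
a dimensional result (e.g. a shear stress in pascal) is produced.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "CiliaParams",
    "FluidParams",
    "BeadParams",
    "DimensionlessGroups",
    "dimensionless_groups",
    "load_config",
]

# unit conversions to SI
UM = 1e-6            # micrometre -> metre
G_PER_CM3 = 1e3      # g/cm^3 -> kg/m^3
CP = 1e-3            # centipoise -> Pa s

#: a/h ratio above which the second-order expansion is flagged as unreliable
EPS_WARN_THRESHOLD = 0.3


class ParameterError(ValueError):
    """A physical parameter violates its validity constraint."""


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ParameterError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class CiliaParams:
    """Geometry and kinematics of the beating ciliated edge.

    Parameters
    ----------
    a : float
        Ciliary beat amplitude (half the major axis of the elliptic tip
        trajectory), in micrometres.
    beta : float
        Ellipse eccentricity, i.e. the ratio of the vertical to horizontal
        semi-axes of the tip trajectory.  Signed: ``beta > 0`` is clockwise
        tip rotation, ``beta < 0`` counterclockwise.
    f : float
        Ciliary beat frequency in hertz.
    lam : float
        Metachronal wavelength in micrometres.
    phi_star : float
        Sliding length of the partial-slip (Robin) wall condition, in
        micrometres.  ``0`` is no slip.
    h : float
        Stagnation height: the distance above the ciliated edge at which the
        fluid velocity and shear vanish, in micrometres.
    """

    a: float
    beta: float
    f: float
    lam: float
    phi_star: float = 0.0
    h: float = 50.0

    def __post_init__(self) -> None:
        _require_positive("a", self.a)
        _require_positive("f", self.f)
        _require_positive("lam", self.lam)
        _require_positive("h", self.h)
        if self.phi_star < 0:
            raise ParameterError(f"phi_star must be >= 0, got {self.phi_star!r}")
        if self.a / self.h > EPS_WARN_THRESHOLD:
            warnings.warn(
                f"a/h = {self.a / self.h:.2f} > {EPS_WARN_THRESHOLD}: the "
                "second-order amplitude expansion assumes a/h << 1 and its "
                "error grows as (a/h)^3",
                stacklevel=2,
            )

    @property
    def omega(self) -> float:
        """Angular beat frequency 2*pi*f, in rad/s."""
        return 2.0 * math.pi * self.f

    @property
    def wave_speed(self) -> float:
        """Metachronal wave speed c = f * lam, in um/s."""
        return self.f * self.lam


@dataclass(frozen=True)
class FluidParams:
    """Newtonian fluid surrounding the cilia (density g/cm^3, viscosity cP)."""

    rho: float = 1.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("rho", self.rho)
        _require_positive("mu", self.mu)

    @property
    def rho_si(self) -> float:
        return self.rho * G_PER_CM3

    @property
    def mu_si(self) -> float:
        return self.mu * CP


@dataclass(frozen=True)
class BeadParams:
    """Spherical tracer micro-bead (radius um, density g/cm^3)."""

    R: float = 2.25
    rho_b: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("R", self.R)
        _require_positive("rho_b", self.rho_b)

    @property
    def mass(self) -> float:
        """Bead mass (4/3) pi R^3 rho_b, in kg."""
        return (4.0 / 3.0) * math.pi * (self.R * UM) ** 3 * self.rho_b * G_PER_CM3


@dataclass(frozen=True)
class DimensionlessGroups:
    """The dimensionless numbers that fully determine the flow solution.

    eps = a/h, k = 2*pi*h/lam, alpha = Womersley number sqrt(rho h^2 omega / mu),
    phi = phi_star/h, and (when bead properties are supplied) the bead Stokes
    number stk = (2/9) R^2 rho_b omega / mu.
    """

    eps: float
    k: float
    alpha: float
    phi: float
    stk: Optional[float] = None


def dimensionless_groups(
    cilia: CiliaParams,
    fluid: FluidParams,
    bead: Optional[BeadParams] = None,
) -> DimensionlessGroups:
    """Derive (eps, k, alpha, phi[, stk]) from the physical parameters."""
    omega = cilia.omega
    h_si = cilia.h * UM
    alpha = math.sqrt(fluid.rho_si * h_si**2 * omega / fluid.mu_si)
    stk = None
    if bead is not None:
        stk = (2.0 / 9.0) * (bead.R * UM) ** 2 * bead.rho_b * G_PER_CM3 * omega / fluid.mu_si
    return DimensionlessGroups(
        eps=cilia.a / cilia.h,
        k=2.0 * math.pi * cilia.h / cilia.lam,
        alpha=alpha,
        phi=cilia.phi_star / cilia.h,
        stk=stk,
    )


_CILIA_KEYS = {"a", "beta", "f", "lam", "phi_star", "h"}
_FLUID_KEYS = {"rho", "mu"}
_BEAD_KEYS = {"R", "rho_b"}


def load_config(path: str | Path, **overrides: float):
    """Read a flat key/value config file (YAML or JSON dialect).

    Recognised keys: a, beta, f, lam, phi_star, h (cilia); rho, mu (fluid);
    R, rho_b (bead).  Keyword ``overrides`` take precedence over the file,
    mirroring command-line flags.  Returns ``(CiliaParams, FluidParams,
    BeadParams | None)``; bead parameters are built only if at least one bead
    key is present.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a flat mapping")
    raw = dict(raw)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - _CILIA_KEYS - _FLUID_KEYS - _BEAD_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    cilia = CiliaParams(**{k: float(raw[k]) for k in _CILIA_KEYS & set(raw)})
    fluid = FluidParams(**{k: float(raw[k]) for k in _FLUID_KEYS & set(raw)})
    bead = None
    if _BEAD_KEYS & set(raw):
        bead = BeadParams(**{k: float(raw[k]) for k in _BEAD_KEYS & set(raw)})
    return cilia, fluid, bead
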