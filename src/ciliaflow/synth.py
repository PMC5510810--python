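"""Synthetic bead-velocity profiles with a controlled noise model.

Emulates the measurement structure of micro-bead tracking next to a ciliated
edge: effective speeds sampled at a set of distances, with independent
Gaussian noise on speed (relative to the wall velocity U0) and optionally on
the measured distance.  Defaults reproduce a typical healthy-edge parameter
set: CBF 10 Hz, CBA 8 um, wavelength 10 um, no slip, stagnation at 50 um.

``closed_form`` mode samples the parabolic law directly; ``traced`` mode
runs actual tracer integrations through the full oscillatory+steady field,
so it carries the (small) contamination from the oscillatory first order and
the exponential streaming tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Tuple

import numpy as np

from .beads import effective_speed_profile
from .fitting import VelocityProfile, predict_U0
from .flow import build_field
from .params import BeadParams, CiliaParams, FluidParams, dimensionless_groups

__all__ = ["SynthConfig", "generate_profile", "default_cilia"]


def default_cilia() -> CiliaParams:
    """Reference beating parameters: 10 Hz, 8 um amplitude, 10 um wave, h=50 um."""
    return CiliaParams(a=8.0, beta=0.0, f=10.0, lam=10.0, phi_star=0.0, h=50.0)


@dataclass
class SynthConfig:
    """Full specification of one synthetic profile draw.

    ``y_range`` is the sampled fraction of [0, h]; ``noise_sigma_rel`` is the
    speed noise standard deviation as a fraction of U0; ``noise_sigma_y`` is
    absolute distance noise in um.  The seed fixes the output bit-for-bit.
    """

    cilia: CiliaParams = dc_field(default_factory=default_cilia)
    fluid: FluidParams = dc_field(default_factory=FluidParams)
    bead: BeadParams = dc_field(default_factory=BeadParams)
    n_points: int = 20
    y_range: Tuple[float, float] = (0.1, 0.9)
    noise_sigma_rel: float = 0.05
    noise_sigma_y: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError(f"n_points must be >= 4, got {self.n_points}")
        lo, hi = self.y_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"y_range must satisfy 0 <= lo < hi <= 1, got {self.y_range}")
        if self.noise_sigma_rel < 0 or self.noise_sigma_y < 0:
            raise ValueError("noise levels must be >= 0")


def generate_profile(
    cfg: SynthConfig, mode: str = "closed_form"
) -> Tuple[VelocityProfile, dict]:
    """Draw one synthetic velocity profile plus its ground-truth record.

    Returns ``(profile, truth)`` where ``truth`` carries the generating U0,
    h, phi* and all parameters, so recovery studies can score the fit.
    """
    if mode not in ("closed_form", "traced"):
        raise ValueError(f"mode must be 'closed_form' or 'traced', got {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    c = cfg.cilia
    U0 = predict_U0(c)
    lo, hi = cfg.y_range
    y = np.linspace(lo * c.h, hi * c.h, cfg.n_points)

    if mode == "closed_form":
        v = U0 * np.clip(1.0 - y / c.h, 0.0, None) ** 2
    else:
        fld = build_field(c, cfg.fluid, cfg.bead)
        prof = effective_speed_profile(fld, y / c.h, stk=0.0)
        y, v = prof.y, prof.v

    v_noisy = v + cfg.noise_sigma_rel * U0 * rng.standard_normal(v.shape)
    y_noisy = y
    if cfg.noise_sigma_y > 0:
        y_noisy = np.clip(y + cfg.noise_sigma_y * rng.standard_normal(y.shape), 0.0, None)

    g = dimensionless_groups(c, cfg.fluid, cfg.bead)
    truth = {
        "U0": U0,
        "h": c.h,
        "phi_star": c.phi_star,
        "a": c.a,
        "beta": c.beta,
        "f": c.f,
        "lam": c.lam,
        "eps": g.eps,
        "k": g.k,
        "alpha": g.alpha,
        "stk": g.stk,
        "mode": mode,
        "seed": cfg.seed,
    }
    return VelocityProfile(y=y_noisy, v=v_noisy), truth
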