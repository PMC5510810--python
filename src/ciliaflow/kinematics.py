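"""Cilium-tip kinematics and the Eulerian expansion of the envelope wall.

The tips of neighbouring cilia, beating with a linear phase lag, form a
continuous undulating envelope.  Its position and velocity, viewed at a fixed
Eulerian station x, are expanded to second order in the amplitude ratio
eps = a/h.  The expansion produces one non-oscillatory term: a steady
horizontal wall velocity of magnitude k at second order, which is the sole
origin of the net fluid transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DimensionlessGroups

__all__ = ["WallState", "tip_position", "wall_state"]


@dataclass(frozen=True)
class WallState:
    """First- and second-order envelope terms at local phase theta = kx + t.

    The physical wall height and velocity are reconstructed as
    ``y_w = eps*yw1 + (eps^2/2)*yw2`` and likewise for (u_w, v_w).
    All fields are dimensionless and 2*pi-periodic in theta.
    """

    theta: np.ndarray
    yw1: np.ndarray
    yw2: np.ndarray
    uw1: np.ndarray
    uw2: np.ndarray
    vw1: np.ndarray
    vw2: np.ndarray


def tip_position(xi, t, g: DimensionlessGroups, beta: float):
    """Dimensionless coordinates of the tip of the cilium centred at xi.

    The tip sweeps an ellipse centred at (xi, 0) with horizontal semi-axis
    eps and vertical semi-axis |beta|*eps; the phase k*xi + t encodes the
    metachronal wave travelling in the -x direction.

    Returns
    -------
    (Xw, Yw) : tuple of arrays
        ``Xw = xi - eps*cos(k*xi + t)``, ``Yw = beta*eps*sin(k*xi + t)``.
    """
    xi = np.asarray(xi, dtype=float)
    phase = g.k * xi + np.asarray(t, dtype=float)
    return xi - g.eps * np.cos(phase), beta * g.eps * np.sin(phase)


def wall_state(theta, beta: float, k: float) -> WallState:
    """Evaluate all six envelope expansion terms at phase theta.

    ``uw2 = k*(1 + cos 2theta)`` carries the steady offset k; its theta-average
    is exactly k, and the average of ``yw2`` is beta*k.  All other terms are
    zero-mean oscillations.
    """
    theta = np.asarray(theta, dtype=float)
    c2 = 1.0 + np.cos(2.0 * theta)
    return WallState(
        theta=theta,
        yw1=beta * np.sin(theta),
        yw2=beta * k * c2,
        uw1=np.sin(theta),
        uw2=k * c2,
        vw1=beta * np.cos(theta),
        vw2=-2.0 * beta * k * np.sin(2.0 * theta),
    )
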