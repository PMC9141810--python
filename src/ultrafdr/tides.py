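"""Tide geometry: the spherical translation factor as a tidal force field.

For an ideal moon of mass m at distance D from an ideal sphere of radius R,
in units where Gm/D^2 = 1 and with z = R/D playing the role of the
noncentrality cos(theta_delta), the horizontal component of the tidal force
at polar angle theta is exactly the spherical (nu2 = 2) t-family
translation factor,

    Th(theta) = (1 - x z) / (1 - 2 x z + z^2)^(3/2),   x = cos(theta),

and the vertical component is Tv = -sin(theta)/(1 - 2 x z + z^2)^(3/2).
Weighted by the central spherical density, Th integrates to exactly 1 for
every R/D in [0, 1); subtracting the unit centrifugal force yields the
asymmetric equatorial bulges of the net field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import central_pdf
from .families import t_family
from .orthopoly import translation_closed_form

__all__ = ["TideGeometry", "tidal_forces", "integrated_horizontal_force",
           "net_force_field"]

_SPHERE = t_family(2.0)  # b = 1/2, the ordinary sphere S^2


@dataclass(frozen=True)
class TideGeometry:
    """Moon-sphere geometry: ratio R/D in [0, 1), units Gm/D^2 = 1."""

    cos_theta_delta: float

    def __post_init__(self):
        if not 0.0 <= self.cos_theta_delta < 1.0:
            raise ValueError("R/D must lie in [0, 1)")


def tidal_forces(geom: TideGeometry, theta):
    """(horizontal, vertical) tidal force components at polar angle theta."""
    theta = np.asarray(theta, dtype=float)
    x, z = np.cos(theta), geom.cos_theta_delta
    th = np.asarray(translation_closed_form(_SPHERE, x, z))
    tv = -np.sin(theta) / (1.0 - 2.0 * x * z + z * z) ** 1.5
    return th, tv


def integrated_horizontal_force(geom: TideGeometry, npoints: int = 256) -> float:
    """Quadrature of Th weighted by the central spherical density over
    theta in [0, pi]; equals 1 for every geometry."""
    x, w = np.polynomial.legendre.leggauss(npoints)  # x = cos(theta) directly
    th, _ = tidal_forces(geom, np.arccos(x))
    return float(np.dot(w, th * central_pdf(_SPHERE, x)))


def net_force_field(geom: TideGeometry, theta) -> pd.DataFrame:
    """Net field after subtracting the unit centrifugal force: columns
    theta, Th, Tv, net_horizontal = Th - 1."""
    th, tv = tidal_forces(geom, theta)
    return pd.DataFrame({"theta": np.asarray(theta, dtype=float),
                         "Th": th, "Tv": tv, "net_horizontal": th - 1.0})
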