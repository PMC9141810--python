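"""Central and noncentral densities, transforms, p-values, and comparisons.

Central densities double as the orthogonal-polynomial weights.  Noncentral
densities are products ``T(x|u) * w(x)`` with the hyperspherical translation
factors of :mod:`ultrafdr.orthopoly`; the classical (translated-normal)
translation factors are provided for comparison, together with the
symmetrized Kullback--Leibler divergence between the two constructions.

The t and F statistics are carried on their compact angle supports
x = cos(theta); :func:`statistic_to_angle` / :func:`angle_to_statistic`
convert to the conventional scales t = sqrt(nu2) x/sqrt(1-x^2) and
F = (nu2/nu1) x^2/(1-x^2).

``pvalue`` is the lower-tail CDF of the central distribution in the
family's own variable; use ``upper_tail_to_statistic`` in the pipeline to
ingest conventional upper-tail p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special as sp
from scipy import stats

from .families import Family, FamilySpec
from .orthopoly import translation_closed_form

__all__ = [
    "central_pdf",
    "noncentral_pdf",
    "classical_translation_factor",
    "statistic_to_angle",
    "angle_to_statistic",
    "pvalue",
    "quantile",
    "kl_classical_vs_ultraspherical",
    "f_translation_integral_oracle",
    "SupportGrid",
    "support_grid",
]

_DENSITY_FLOOR = 1e-300


def central_pdf(spec: FamilySpec, r):
    """Normalized central density (= polynomial weight) at points ``r``.

    Points outside the support return density 0 by convention, so binned
    empirical data touching a boundary never raises.
    """
    r = np.asarray(r, dtype=float)
    if spec.family is Family.T:
        b = spec.b
        const = math.exp(sp.gammaln(b + 1) - sp.gammaln(0.5) - sp.gammaln(b + 0.5))
        inside = np.abs(r) < 1.0
        out = np.where(inside, const * np.abs(1.0 - r * r) ** (b - 0.5), 0.0)
    elif spec.family is Family.NORMAL:
        out = np.asarray(stats.norm.pdf(r))
    elif spec.family is Family.F:
        a, b = spec.a, spec.b
        const = 2.0 * math.exp(sp.gammaln(a + b + 2) - sp.gammaln(a + 1) - sp.gammaln(b + 1))
        inside = (r >= 0.0) & (r < 1.0)
        rr = np.where(inside, r, 0.5)
        out = np.where(inside, const * rr ** (2 * a + 1) * (1.0 - rr * rr) ** b, 0.0)
    else:
        out = np.asarray(stats.chi2.pdf(r, spec.nu1))
    return out if out.shape else float(out)


def noncentral_pdf(spec: FamilySpec, r, u):
    """Hyperspherical noncentral density ``T(r|u) * w(r)``; integrates to 1
    in r for every u in the prior domain."""
    r = np.asarray(r, dtype=float)
    w = np.asarray(central_pdf(spec, r))
    out = np.where(w > 0.0, np.asarray(translation_closed_form(spec, r, u)) * w, 0.0)
    return out if out.shape else float(out)


def classical_translation_factor(spec: FamilySpec, r, nc):
    """Classical translation factor E(r|ro) e^{-ro^2/2} from the
    translated-normal construction; ``nc`` is family-native (delta for
    t/normal, Lambda for F/chi2).

    For the normal and chi-square families this coincides exactly with the
    hyperspherical factor; for t and F it differs at low degrees of freedom.
    """
    r = np.asarray(r, dtype=float)
    if spec.family is Family.NORMAL:
        out = np.exp(r * nc - 0.5 * nc * nc)
    elif spec.family is Family.CHI2:
        out = sp.hyp0f1(spec.nu1 / 2.0, nc * r / 4.0) * np.exp(-nc / 2.0)
    elif spec.family is Family.T:
        nu2, d = spec.nu2, float(nc)
        arg = 0.5 * d * d * r * r
        even = sp.hyp1f1((nu2 + 1) / 2.0, 0.5, arg)
        odd = (math.sqrt(2.0) * d * r
               * math.exp(sp.gammaln((nu2 + 2) / 2.0) - sp.gammaln((nu2 + 1) / 2.0))
               * sp.hyp1f1((nu2 + 2) / 2.0, 1.5, arg))
        out = (even + odd) * np.exp(-0.5 * d * d)
    else:
        nu1, nu2, lam = spec.nu1, spec.nu2, float(nc)
        if lam < 0:
            raise ValueError("Lambda must be nonnegative")
        out = sp.hyp1f1((nu1 + nu2) / 2.0, nu1 / 2.0, 0.5 * lam * r * r) * np.exp(-lam / 2.0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"classical translation factor overflowed for the {spec.family.value} "
            f"family at nc={nc}")
    return out if np.asarray(out).shape else float(out)


def statistic_to_angle(spec: FamilySpec, value):
    """Map a conventional t or F statistic to the angle variable x = cos(theta)."""
    value = np.asarray(value, dtype=float)
    if spec.family is Family.T:
        out = value / np.sqrt(value * value + spec.nu2)
    elif spec.family is Family.F:
        if np.any(value < 0):
            raise ValueError("F statistics must be nonnegative")
        out = np.sqrt(spec.nu1 * value / (spec.nu1 * value + spec.nu2))
    else:
        out = value  # normal / chi2 statistics are already in their own scale
    return out if out.shape else float(out)


def angle_to_statistic(spec: FamilySpec, x):
    """Inverse of :func:`statistic_to_angle` (t = sqrt(nu2) x / sin(theta))."""
    x = np.asarray(x, dtype=float)
    if spec.family is Family.T:
        out = math.sqrt(spec.nu2) * x / np.sqrt(1.0 - x * x)
    elif spec.family is Family.F:
        out = (spec.nu2 / spec.nu1) * x * x / (1.0 - x * x)
    else:
        out = x
    return out if out.shape else float(out)


def pvalue(spec: FamilySpec, r):
    """Lower-tail CDF of the central distribution in the family variable."""
    r = np.asarray(r, dtype=float)
    if spec.family is Family.T:
        out = stats.t.cdf(angle_to_statistic(spec, np.clip(r, -1.0, 1.0)), spec.nu2)
    elif spec.family is Family.NORMAL:
        out = stats.norm.cdf(r)
    elif spec.family is Family.F:
        out = stats.f.cdf(angle_to_statistic(spec, np.clip(r, 0.0, 1.0)), spec.nu1, spec.nu2)
    else:
        out = stats.chi2.cdf(r, spec.nu1)
    out = np.asarray(out)
    return out if out.shape else float(out)


def quantile(spec: FamilySpec, p):
    """Central quantile; inverse of :func:`pvalue` (p clipped to [1e-12, 1-1e-12])."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    if spec.family is Family.T:
        out = statistic_to_angle(spec, stats.t.ppf(p, spec.nu2))
    elif spec.family is Family.NORMAL:
        out = stats.norm.ppf(p)
    elif spec.family is Family.F:
        out = statistic_to_angle(spec, stats.f.ppf(p, spec.nu1, spec.nu2))
    else:
        out = stats.chi2.ppf(p, spec.nu1)
    out = np.asarray(out)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class SupportGrid:
    """Quadrature nodes/weights adapted to a family support."""

    nodes: np.ndarray
    weights: np.ndarray

    def integrate(self, values) -> float:
        return float(np.dot(self.weights, values))


def support_grid(spec: FamilySpec, npoints: int = 256, reach: float = 12.0) -> SupportGrid:
    """Gauss-Legendre rule over the support (infinite supports are truncated
    at ``reach`` standard scales; enlarge for strongly noncentral work)."""
    nodes, weights = np.polynomial.legendre.leggauss(npoints)
    if spec.family is Family.T:
        return SupportGrid(nodes, weights)
    if spec.family is Family.F:
        return SupportGrid(0.5 * (nodes + 1.0), 0.5 * weights)
    if spec.family is Family.NORMAL:
        return SupportGrid(reach * nodes, reach * weights)
    hi = float(spec.nu1 + reach * math.sqrt(2.0 * spec.nu1) + reach)
    return SupportGrid(0.5 * hi * (nodes + 1.0), 0.5 * hi * weights)


def kl_classical_vs_ultraspherical(spec: FamilySpec, nc, npoints: int = 512) -> float:
    """Symmetrized KL divergence between the hyperspherical and classical
    noncentral densities at family-native noncentrality ``nc``.

    Zero when the densities coincide (always for normal/chi2, and for t/F
    at nc = 0); grows at small degrees of freedom and large noncentrality.
    """
    if spec.family in (Family.NORMAL, Family.CHI2):
        return 0.0
    grid = support_grid(spec, npoints)
    u = spec.native_to_u(float(nc))
    ultra = np.maximum(np.asarray(noncentral_pdf(spec, grid.nodes, u)), _DENSITY_FLOOR)
    classical = np.asarray(classical_translation_factor(spec, grid.nodes, nc)) \
        * np.asarray(central_pdf(spec, grid.nodes))
    if np.any(classical <= 0.0):
        warnings.warn("classical density clipped at machine floor", RuntimeWarning)
    classical = np.maximum(classical, _DENSITY_FLOOR)
    # renormalize on the grid so truncation of infinite tails cancels
    ultra = ultra / grid.integrate(ultra)
    classical = classical / grid.integrate(classical)
    return float(grid.integrate((ultra - classical) * np.log(ultra / classical)))


def f_translation_integral_oracle(spec: FamilySpec, x, u, npoints: int = 400) -> float:
    """F translation factor by brute-force adaptive quadrature of the
    hyperspherical integral over the inner angle (test oracle; requires
    a > -1/2 so the inner Gegenbauer weight is a proper density)."""
    if spec.family is not Family.F:
        raise ValueError("integral oracle is defined for the F family only")
    a, b = spec.a, spec.b
    if a <= -0.5:
        raise ValueError("integral oracle requires a > -1/2")
    z = math.sqrt(float(u))
    const = math.exp(sp.gammaln(a + 1) - sp.gammaln(0.5) - sp.gammaln(a + 0.5))
    from scipy.integrate import quad

    def integrand(xi):
        return (const * (1.0 - xi * xi) ** (a - 0.5) * (1.0 - x * xi * z)
                / (1.0 - 2.0 * x * xi * z + z * z) ** (a + b + 2.0))

    val, err = quad(integrand, -1.0, 1.0, limit=npoints)
    if err > 1e-8:
        raise FloatingPointError(f"quadrature failure, error estimate {err}")
    return float(val)
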