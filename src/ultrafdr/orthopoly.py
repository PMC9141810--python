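"""Orthogonal polynomials under the central-distribution weight convention.

Each statistic family owns a classical polynomial family whose defining
weight is the *normalized central distribution* of the statistic:

========  =========================  ==========================================
family    polynomials P_n            squared norm ||P_n||^2 under that weight
========  =========================  ==========================================
t         Gegenbauer  C_n^(b)(x)     b/(b+n) * (2b)_n / n!
normal    Hermite     He_n(r)        n!
F         F_n^(a,b)(x^2)             (a+b+1)/(a+b+1+2n) * (a+b+1)_n (b+1)_n
                                       / ((a+1)_n n!)
chi2      Laguerre    L_n^(a)(r/2)   (a+1)_n / n!
========  =========================  ==========================================

The F-family polynomial is a rescaled shifted Jacobi polynomial,
``F_n^(a,b)(x^2) = (-1)^n (a+b+1)_n/(a+1)_n P_n^(a,b)(1-2x^2)``.

The noncentral translation factor of each family is the generating function

    T(x | u) = sum_n c_n P_n(x) u**n

in the expansion variable u of :class:`~ultrafdr.families.FamilySpec`, with
coefficients ``c_n`` from :func:`expansion_coefficient`.  The closed forms
are algebraic for t and normal, a confluent ``0F1`` for chi-square, and an
exact one-dimensional Gauss--Jacobi quadrature of the hyperspherical
integral representation for F (whose hypergeometric reduction is not used).
All public functions are vectorized over the point argument.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy import special as sp

from .families import Family, FamilySpec

__all__ = [
    "log_pochhammer",
    "pochhammer",
    "poly_eval",
    "poly_eval_all",
    "poly_norm",
    "expansion_coefficient",
    "expansion_coefficients",
    "translation_closed_form",
    "translation_series",
]


def log_pochhammer(x: float, n: int) -> float:
    """log of the rising factorial (x)_n = Gamma(x+n)/Gamma(x), x > 0."""
    if n == 0:
        return 0.0
    return float(sp.gammaln(x + n) - sp.gammaln(x))


def pochhammer(x: float, n: int) -> float:
    """Rising factorial (x)_n, computed in log-Gamma space for x > 0."""
    if x > 0:
        return float(np.exp(log_pochhammer(x, n)))
    # x <= 0 can occur transiently (e.g. a = -1/2 gives (a+1/2)_n); fall back
    # to the product form, which is exact for small n.
    out = 1.0
    for k in range(n):
        out *= x + k
    return out


def _check_order(n: int) -> None:
    if n < 0 or int(n) != n:
        raise ValueError(f"polynomial order must be a nonnegative integer, got {n}")


def poly_eval(spec: FamilySpec, n: int, x):
    """Evaluate the order-n family polynomial at points ``x`` in the support.

    For the F family the polynomial is F_n^(a,b) evaluated in x**2; for the
    chi-square family the Laguerre polynomial is evaluated at r/2.
    """
    _check_order(n)
    x = np.asarray(x, dtype=float)
    if spec.family is Family.T:
        return np.asarray(sp.eval_gegenbauer(n, spec.b, x), dtype=float)
    if spec.family is Family.NORMAL:
        return np.asarray(sp.eval_hermitenorm(n, x), dtype=float)
    if spec.family is Family.F:
        a, b = spec.a, spec.b
        pref = (-1.0) ** n * np.exp(log_pochhammer(a + b + 1, n) - log_pochhammer(a + 1, n))
        return pref * np.asarray(sp.eval_jacobi(n, a, b, 1.0 - 2.0 * x * x), dtype=float)
    return np.asarray(sp.eval_genlaguerre(n, spec.a, x / 2.0), dtype=float)


def poly_eval_all(spec: FamilySpec, order: int, x) -> np.ndarray:
    """Stack ``poly_eval(spec, n, x)`` for n = 0..order; shape (order+1, *x.shape)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.stack([poly_eval(spec, n, x) for n in range(order + 1)])


def poly_norm(spec: FamilySpec, n: int) -> float:
    """Squared norm ||P_n||^2 under the family's central-distribution weight."""
    _check_order(n)
    lnfact = float(sp.gammaln(n + 1))
    if spec.family is Family.T:
        b = spec.b
        return b / (b + n) * float(np.exp(log_pochhammer(2 * b, n) - lnfact))
    if spec.family is Family.NORMAL:
        return float(np.exp(lnfact))
    if spec.family is Family.F:
        a, b = spec.a, spec.b
        s = a + b + 1
        return s / (s + 2 * n) * float(
            np.exp(log_pochhammer(s, n) + log_pochhammer(b + 1, n)
                   - log_pochhammer(a + 1, n) - lnfact))
    return float(np.exp(log_pochhammer(spec.a + 1, n) - lnfact))


def expansion_coefficient(spec: FamilySpec, n: int) -> float:
    """Coefficient c_n of the generating function T(x|u) = sum c_n P_n(x) u^n."""
    _check_order(n)
    if spec.family is Family.T:
        return (2 * spec.b + n) / (2 * spec.b)
    if spec.family is Family.NORMAL:
        return float(np.exp(-sp.gammaln(n + 1)))
    if spec.family is Family.F:
        s = spec.a + spec.b + 1
        return (s + n) / s
    return (-1.0) ** n * float(np.exp(-log_pochhammer(spec.a + 1, n)))


def expansion_coefficients(spec: FamilySpec, order: int) -> np.ndarray:
    """Vector (c_0, ..., c_order)."""
    return np.array([expansion_coefficient(spec, n) for n in range(order + 1)])


def _check_u(spec: FamilySpec, u: np.ndarray) -> None:
    lo, hi = spec.prior_domain
    if np.any(u < lo) or np.any(u > hi) or (spec.compact and np.any(np.abs(u) >= 1.0)):
        raise ValueError(
            f"expansion variable u outside the prior domain {spec.prior_domain} "
            f"of the {spec.family.value} family")


@functools.lru_cache(maxsize=16)
def _gauss_jacobi_rule(a: float, npoints: int):
    """Nodes/weights for integration against the normalized weight
    Gamma(a+1)/(Gamma(1/2)Gamma(a+1/2)) (1-xi^2)^(a-1/2) on (-1, 1)."""
    nodes, weights = sp.roots_jacobi(npoints, a - 0.5, a - 0.5)
    const = float(np.exp(sp.gammaln(a + 1) - sp.gammaln(0.5) - sp.gammaln(a + 0.5)))
    return nodes, weights * const


def _t_closed(b: float, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    return (1.0 - x * z) / (1.0 - 2.0 * x * z + z * z) ** (b + 1.0)


def _f_closed(spec: FamilySpec, x: np.ndarray, u: np.ndarray, npoints: int = 160) -> np.ndarray:
    """F translation factor by the exact inner-sphere integral,

        T_F(x|z) = int_{-1}^{1} (1 - x xi z) / (1 - 2 x xi z + z^2)^(a+b+2)
                   w_t^(a)(xi) d(xi),   z = sqrt(u),

    computed with a Gauss-Jacobi rule matched to the weight (exact for the
    polynomial part, ~1e-13 overall for z bounded away from 1).  At
    a = -1/2 (nu1 = 1) the weight degenerates to half point masses at
    xi = +-1 and the integral reduces to the two-term reflected sum.
    """
    a, b = spec.a, spec.b
    z = np.sqrt(u)
    if a == -0.5:
        bt = b + 0.5  # t-family shape at the same nu2
        return 0.5 * (_t_closed(bt, x, z) + _t_closed(bt, -x, z))
    if a < -0.5:
        # weight (1-xi^2)^(a-1/2) with exponent <= -1 is handled by the
        # series, which converges for z < 1
        return _series_sum(spec, x, u, adaptive=True)
    nodes, weights = _gauss_jacobi_rule(a, npoints)
    xz = np.multiply.outer(x * z, nodes)          # (..., npoints)
    integrand = (1.0 - xz) / (1.0 - 2.0 * xz + np.expand_dims(z * z, -1)) ** (a + b + 2.0)
    return integrand @ weights


def _series_sum(spec: FamilySpec, x: np.ndarray, u: np.ndarray,
                order: int | None = None, adaptive: bool = False) -> np.ndarray:
    terms_shape = np.broadcast(x, u).shape
    out = np.zeros(terms_shape)
    nmax = 2000 if adaptive else order
    for n in range(nmax + 1):
        term = expansion_coefficient(spec, n) * poly_eval(spec, n, x) * u ** n
        out = out + term
        if adaptive and n > 20 and np.all(np.abs(term) <= 1e-15 * np.maximum(np.abs(out), 1e-300)):
            break
    return out


def translation_closed_form(spec: FamilySpec, x, u):
    """Closed-form translation factor T(x|u) >= 0 converting the central
    density into its noncentral counterpart (u is the expansion variable)."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    _check_u(spec, u)
    if spec.family is Family.T:
        out = _t_closed(spec.b, x, u)
    elif spec.family is Family.NORMAL:
        out = np.exp(x * u - 0.5 * u * u)
    elif spec.family is Family.F:
        out = _f_closed(spec, x, u)
    else:  # chi2: 0F1(; a+1; Lambda r / 4) e^(-Lambda/2), Lambda = 2u
        out = sp.hyp0f1(spec.a + 1.0, u * x / 2.0) * np.exp(-u)
    return out if out.shape else float(out)


def translation_series(spec: FamilySpec, x, u, order: int):
    """Partial sum sum_{n<=order} c_n P_n(x) u^n of the generating function.

    Converges to :func:`translation_closed_form` as the order grows for u
    strictly inside the prior domain.
    """
    _check_order(order)
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    _check_u(spec, u)
    out = _series_sum(spec, x, u, order=order)
    return out if out.shape else float(out)
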