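"""Maximum-entropy (Gibbs) priors and Bayes-factor / local-fdr models.

The empirical density of a column of test statistics is written as
``rho(r) = BF(r) w(r)`` with ``w`` the central density.  Expanding the
Bayes factor on the family polynomials gives coefficients

    beta_n = mean(P_n(r_i)) / (c_n ||P_n||^2),

which, by orthogonality, equal the moments ``E_pi[u^n]`` of the prior over
the expansion variable u.  The data-constrained maximal-entropy prior is
the Gibbs measure ``pi(u) = exp(sum_n lam_n u^n) / Z`` whose dual
coefficients lam_n minimize the convex Gibbs potential

    G(lam) = log Z(lam) - sum_n lam_n beta_n,

whose gradient is the moment mismatch ``E_pi[u^n] - beta_n`` and whose
Hessian is the (PSD) covariance of the monomials under pi -- the problem is
solved with an exact-Hessian trust-region Newton method on coefficients
rescaled by powers of the domain half-width for conditioning.

Two routes then model the Bayes factor: the PRIOR route integrates the
analytic translation factor against the fitted Gibbs prior (immune to the
Gibbs phenomenon on the compact t/F supports, the default there), and the
MOMENT route sums the truncated polynomial expansion directly (exact in
expectation, the default for normal/chi2).  The local false discovery rate
is ``fdr(p) = 1 / (1 + BF(p))``.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .distributions import central_pdf, quantile
from .families import Family, FamilySpec, spec_from_name
from .orthopoly import (expansion_coefficients, poly_eval_all, poly_norm,
                        translation_closed_form)

logger = logging.getLogger(__name__)

__all__ = [
    "BetaCoefficients",
    "DualCoefficients",
    "GibbsPrior",
    "Route",
    "BayesFactorModel",
    "estimate_beta",
    "default_prior_domain",
    "gibbs_potential",
    "fit_gibbs_prior",
    "fit_model",
    "bayes_factor",
    "pvalue_density",
    "local_fdr",
    "model_fit_kl",
    "model_to_json",
    "model_from_json",
]


# --------------------------------------------------------------------------
# beta coefficients (prior moments in u, estimated in random-variable space)

@dataclass
class BetaCoefficients:
    """Bayes-factor expansion coefficients beta_0..beta_N with standard errors."""

    spec: FamilySpec
    beta: np.ndarray
    se: np.ndarray
    n_samples: int
    n_rejected: int = 0

    @property
    def order(self) -> int:
        return len(self.beta) - 1

    def truncated(self, order: int) -> "BetaCoefficients":
        if order > self.order:
            raise ValueError(f"cannot extend order {self.order} to {order}")
        return BetaCoefficients(self.spec, self.beta[:order + 1],
                                self.se[:order + 1], self.n_samples, self.n_rejected)


def estimate_beta(samples, spec: FamilySpec, order: int) -> BetaCoefficients:
    """Estimate beta_n = mean(P_n(r_i)) / (c_n ||P_n||^2) from raw samples.

    Samples outside the open support are rejected (their count is logged and
    recorded); beta_0 is 1 exactly by construction.
    """
    if order < 1:
        raise ValueError("expansion order must be >= 1")
    r = np.asarray(samples, dtype=float).ravel()
    lo, hi = spec.support
    keep = np.isfinite(r) & (r > lo) & (r < hi)
    if spec.family in (Family.F, Family.CHI2):
        keep |= r == 0.0
    rejected = int(r.size - keep.sum())
    r = r[keep]
    if rejected:
        logger.info("estimate_beta: rejected %d of %d values outside the support",
                    rejected, rejected + r.size)
    if r.size < 100:
        raise ValueError(f"need at least 100 in-support samples, got {r.size}")
    P = poly_eval_all(spec, order, r)                          # (order+1, n)
    scale = np.array([expansion_coefficients(spec, order)[n] * poly_norm(spec, n)
                      for n in range(order + 1)])
    beta = P.mean(axis=1) / scale
    se = P.std(axis=1, ddof=1) / np.sqrt(r.size) / np.abs(scale)
    beta[0], se[0] = 1.0, 0.0
    return BetaCoefficients(spec, beta, se, int(r.size), rejected)


def default_prior_domain(spec: FamilySpec, samples=None) -> tuple[float, float]:
    """Integration domain for the prior over u.

    The compact t/F domains are the family's own; the infinite normal and
    chi-square domains are truncated a little beyond the data range (the
    polynomial tilt need not be integrable on the full line).
    """
    if spec.family is Family.T:
        return (-1.0, 1.0)
    if spec.family is Family.F:
        return (0.0, 1.0)
    if samples is None or len(samples) == 0:
        return (-6.0, 6.0) if spec.family is Family.NORMAL else (0.0, 10.0)
    r = np.asarray(samples, dtype=float)
    if spec.family is Family.NORMAL:
        m = float(np.nanmax(np.abs(r))) + 2.0
        return (-m, m)
    return (0.0, (float(np.nanmax(r)) + 4.0) / 2.0)  # u = Lambda/2


# --------------------------------------------------------------------------
# Gibbs prior via convex duality

@dataclass
class DualCoefficients:
    """Entropic-dual expansion coefficients lam_1..lam_N (lam_0 pinned to 0)."""

    spec: FamilySpec
    lam: np.ndarray                      # length N, coefficients of u^1..u^N
    prior_domain: tuple[float, float]
    grad_norm: float = np.nan

    @property
    def order(self) -> int:
        return len(self.lam)


@dataclass
class GibbsPrior:
    """Maximal-entropy prior pi(u) on a quadrature grid of its domain."""

    dual: DualCoefficients
    nodes: np.ndarray
    quad_weights: np.ndarray
    log_z: float
    moment_residual: float = np.nan

    @property
    def spec(self) -> FamilySpec:
        return self.dual.spec

    def log_density(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        powers = np.stack([u ** n for n in range(1, self.dual.order + 1)])
        return self.dual.lam @ powers - self.log_z

    def density(self, u) -> np.ndarray:
        """Normalized prior density over u (nonnegative by construction)."""
        return np.exp(self.log_density(u))

    @property
    def masses(self) -> np.ndarray:
        """Probability mass attached to each quadrature node (sums to ~1)."""
        return self.quad_weights * self.density(self.nodes)

    def moment(self, n: int) -> float:
        m = self.masses
        return float(np.dot(m, self.nodes ** n) / m.sum())

    def mean(self) -> float:
        return self.moment(1)


def _grid(domain: tuple[float, float], npoints: int):
    nodes, weights = np.polynomial.legendre.leggauss(npoints)
    lo, hi = domain
    half = 0.5 * (hi - lo)
    return lo + half * (nodes + 1.0), half * weights


def gibbs_potential(lam, beta: BetaCoefficients,
                    prior_domain: tuple[float, float] | None = None,
                    npoints: int = 512):
    """Gibbs potential G(lam) = log Z - sum lam_n beta_n, with its gradient.

    ``lam`` holds the coefficients of u^1..u^N (lam_0 is not a free
    parameter: beta_0 = 1 makes it cancel between the two terms).
    Log-sum-exp stabilized; returns ``(value, gradient)``.
    """
    lam = np.asarray(lam, dtype=float)
    domain = prior_domain or default_prior_domain(beta.spec)
    nodes, weights = _grid(domain, npoints)
    powers = np.stack([nodes ** n for n in range(1, len(lam) + 1)])
    tilt = lam @ powers
    if not np.all(np.isfinite(tilt)):
        bad = int(np.argmax(~np.isfinite(lam))) + 1
        raise FloatingPointError(f"non-finite tilt; offending coefficient lam_{bad}")
    log_z = logsumexp(tilt, b=weights)
    if not np.isfinite(log_z):
        raise FloatingPointError("partition function overflowed despite stabilization")
    pi = np.exp(tilt - log_z) * weights
    moments = powers @ pi
    value = float(log_z - np.dot(lam, beta.beta[1:len(lam) + 1]))
    grad = moments - beta.beta[1:len(lam) + 1]
    return value, grad


def _legendre_basis_matrix(order: int, domain: tuple[float, float]) -> np.ndarray:
    """Rows k = 1..order: u-monomial coefficients (u^0..u^order) of the
    Legendre polynomial Leg_k affinely mapped onto ``domain``."""
    A = np.zeros((order, order + 1))
    for k in range(1, order + 1):
        leg = np.polynomial.legendre.Legendre(np.eye(order + 1)[k], domain=list(domain))
        c = leg.convert(kind=np.polynomial.polynomial.Polynomial).coef
        A[k - 1, :len(c)] = c
    return A


def fit_gibbs_prior(beta: BetaCoefficients,
                    prior_domain: tuple[float, float] | None = None,
                    npoints: int = 512,
                    gtol: float = 1e-9,
                    maxiter: int = 500,
                    x0=None) -> GibbsPrior:
    """Minimize the Gibbs potential over the dual coefficients.

    The problem is convex (Hessian = covariance of the basis functions under
    the tilted measure, PSD); for any moment vector in the interior of the
    moment space the optimum is finite, independent of ``x0``, and satisfies
    the moment-matching condition E_pi[u^n] = beta_n, whose residual is
    stored on the returned prior.  Moment vectors on (or, through sampling
    noise, outside) the boundary -- e.g. those of a point mass -- have their
    optimum at infinity; the fit then stops at ``maxiter`` with a small but
    nonzero gradient and a warning, which is the correct behaviour for
    nearly-degenerate priors.

    The optimization runs in a Legendre basis of the rescaled domain for
    conditioning; coefficients are converted back to the monomial dual.
    """
    spec = beta.spec
    domain = prior_domain or default_prior_domain(spec)
    order = beta.order
    nodes, weights = _grid(domain, npoints)
    # work in Legendre polynomials of the affinely mapped domain: their
    # near-orthogonality keeps the Hessian well conditioned at high order
    upow = np.stack([nodes ** n for n in range(order + 1)])
    A = _legendre_basis_matrix(order, domain)              # (order, order+1)
    basis = A @ upow                                       # Leg_k at the nodes
    target = A @ beta.beta                                 # E-data of each Leg_k
    log_w = np.log(weights)

    def objective(gam):
        tilt = gam @ basis + log_w
        log_z = logsumexp(tilt)
        pi = np.exp(tilt - log_z)
        mom = basis @ pi
        val = log_z - float(np.dot(gam, target))
        grad = mom - target
        hess = (basis * pi) @ basis.T - np.outer(mom, mom)
        return val, grad, hess

    def fun(gam):
        v, g, _ = objective(gam)
        return v, g

    def hess(gam):
        return objective(gam)[2]

    if x0 is None:
        gam0 = np.zeros(order)
    else:  # x0 given in the monomial dual; convert to the Legendre basis
        gam0 = np.linalg.lstsq(A[:, 1:].T, np.asarray(x0, dtype=float),
                               rcond=None)[0]
    gam, gnorm = gam0, np.inf
    for _ in range(4):  # restarts reset the trust radius on slow tail phases
        res = minimize(fun, gam, jac=True, hess=hess, method="trust-exact",
                       options={"gtol": gtol, "maxiter": maxiter})
        new_norm = float(np.linalg.norm(objective(res.x)[1]))
        if not np.isfinite(new_norm) or new_norm > gnorm * 0.9:
            gam = res.x if new_norm < gnorm else gam
            gnorm = min(gnorm, new_norm)
            break
        gam, gnorm = res.x, new_norm
        if gnorm <= gtol:
            break
    val, grad, _ = objective(gam)
    gnorm = float(np.linalg.norm(grad))
    # the basis functions are bounded by 1 on the domain, so a gradient of
    # order 1 means the (noisy) moment target lies far outside the feasible
    # set and the returned measure is meaningless; smaller stalls indicate a
    # target on or just past the moment-space boundary (degenerate priors),
    # where the best-approximating concentrated measure is still the right
    # answer and is returned with a warning.
    if not np.isfinite(gnorm) or gnorm >= 1.0 or val > objective(np.zeros(order))[0] + 1e-12:
        raise RuntimeError(
            f"Gibbs-potential minimization did not converge: |grad| = {gnorm:.3e}")
    if gnorm > 10 * gtol:
        logger.warning("Gibbs fit stopped with |grad| = %.3e (moment vector at or "
                       "near the boundary of the moment space)", gnorm)
    mono = gam @ A                                         # coefficients of u^0..u^order
    lam = mono[1:]  # the constant part is absorbed by the normalization
    tilt = lam @ upow[1:]
    log_z = float(logsumexp(tilt, b=weights))
    prior = GibbsPrior(DualCoefficients(spec, lam, domain, gnorm),
                       nodes, weights, log_z)
    resid = max(abs(prior.moment(n) - beta.beta[n]) for n in range(1, order + 1))
    prior.moment_residual = float(resid)
    return prior


# --------------------------------------------------------------------------
# Bayes-factor models

class Route(str, enum.Enum):
    PRIOR = "prior"    # integrate the analytic translation factor against pi
    MOMENT = "moment"  # truncated polynomial expansion sum c_n beta_n P_n(r)


def default_route(spec: FamilySpec) -> Route:
    """Prior route on the compact t/F supports (Gibbs-phenomenon-free),
    moment route for normal/chi2."""
    return Route.PRIOR if spec.compact else Route.MOMENT


@dataclass
class BayesFactorModel:
    """A fitted Bayes-factor model: BF(r), BF(p), fdr(p), modeled density."""

    spec: FamilySpec
    route: Route
    beta: BetaCoefficients
    prior: GibbsPrior | None = None
    clip_fraction: float = field(default=0.0)

    @property
    def order(self) -> int:
        return self.beta.order


def fit_model(samples, spec: FamilySpec, order: int = 8,
              route: Route | None = None,
              prior_domain: tuple[float, float] | None = None,
              **fit_kwargs) -> BayesFactorModel:
    """Estimate beta, fit the Gibbs prior when needed, assemble the model."""
    beta = estimate_beta(samples, spec, order)
    route = Route(route) if route is not None else default_route(spec)
    domain = prior_domain or default_prior_domain(spec, np.asarray(samples, dtype=float))
    prior = fit_gibbs_prior(beta, prior_domain=domain, **fit_kwargs)
    model = BayesFactorModel(spec, route, beta, prior)
    model.clip_fraction = _clip_fraction(model)
    if model.clip_fraction > 0:
        logger.info("moment-route BF negative on %.2f%% of the support (clipped)",
                    100 * model.clip_fraction)
    return model


def bayes_factor(model: BayesFactorModel, r, clip: bool = False):
    """Bayes factor BF(r) by the model's route (vectorized over r).

    The truncated moment route is not sign-constrained; with ``clip=True``
    negative values are clipped to 0 (used for densities and fdr).
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    if model.route is Route.MOMENT:
        P = poly_eval_all(model.spec, model.order, r)
        c = expansion_coefficients(model.spec, model.order)
        out = (c * model.beta.beta) @ P
    else:
        if model.prior is None:
            raise ValueError("prior route requires a fitted Gibbs prior")
        masses = model.prior.masses
        masses = masses / masses.sum()
        T = np.stack([np.asarray(translation_closed_form(model.spec, r, u))
                      for u in model.prior.nodes])
        out = masses @ T
    if clip:
        out = np.maximum(out, 0.0)
    out = np.asarray(out)
    return float(out.reshape(-1)[0]) if scalar else out


def _clip_fraction(model: BayesFactorModel, npoints: int = 801) -> float:
    lo, hi = model.spec.support
    if model.spec.family is Family.NORMAL:
        lo, hi = -10.0, 10.0
    elif model.spec.family is Family.CHI2:
        hi = model.spec.nu1 + 12.0 * np.sqrt(2 * model.spec.nu1) + 12.0
    eps = (hi - lo) * 1e-6
    grid = np.linspace(lo + eps, hi - eps, npoints)
    bf = np.asarray(bayes_factor(model, grid))
    return float(np.mean(bf < 0.0))


def pvalue_density(model: BayesFactorModel, p):
    """Modeled p-value density rho(p) = BF(quantile(p)); 1 under the null."""
    r = quantile(model.spec, p)
    return bayes_factor(model, r, clip=True)


def local_fdr(model: BayesFactorModel, p):
    """Local false discovery rate fdr(p) = 1 / (1 + BF(p)), in (0, 1]."""
    bf = np.asarray(pvalue_density(model, p), dtype=float)
    out = 1.0 / (1.0 + bf)
    return out if out.shape else float(out)


def model_fit_kl(samples, model: BayesFactorModel, bins: int = 200,
                 smooth: float = 1e-12) -> float:
    """KL(empirical || model) of binned statistic densities.

    Empty bins are add-``smooth`` regularized.  Decreases (weakly) with the
    expansion order on well-behaved data down to a binning-noise floor.
    """
    r = np.asarray(samples, dtype=float)
    lo, hi = model.spec.support
    lo = max(lo, float(np.min(r)) - 1e-9)
    hi = min(hi, float(np.max(r)) + 1e-9)
    counts, edges = np.histogram(r, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    p_emp = counts / counts.sum()
    q = np.asarray(bayes_factor(model, centers, clip=True)) \
        * np.asarray(central_pdf(model.spec, centers)) * widths
    p_emp = np.maximum(p_emp, smooth)
    q = np.maximum(q / q.sum(), smooth)
    p_emp = p_emp / p_emp.sum()
    return float(np.sum(p_emp * np.log(p_emp / q)))


# --------------------------------------------------------------------------
# serialization

def model_to_json(model: BayesFactorModel) -> str:
    """Serialize a fitted model to the documented JSON schema."""
    spec = model.spec
    doc = {
        "family": spec.family.value,
        "nu1": None if np.isnan(spec.nu1) else spec.nu1,
        "nu2": None if np.isnan(spec.nu2) else spec.nu2,
        "order": model.order,
        "route": model.route.value,
        "beta": model.beta.beta.tolist(),
        "beta_se": model.beta.se.tolist(),
        "n_samples": model.beta.n_samples,
        "lambda": model.prior.dual.lam.tolist() if model.prior else None,
        "prior_domain": list(model.prior.dual.prior_domain) if model.prior else None,
        "moment_residual": None if model.prior is None else model.prior.moment_residual,
        "clip_fraction": model.clip_fraction,
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> BayesFactorModel:
    doc = json.loads(text)
    spec = spec_from_name(doc["family"], doc.get("nu1"), doc.get("nu2"))
    beta = BetaCoefficients(spec, np.asarray(doc["beta"]), np.asarray(doc["beta_se"]),
                            doc["n_samples"])
    prior = None
    if doc.get("lambda") is not None:
        prior = fit_gibbs_prior(beta, prior_domain=tuple(doc["prior_domain"]))
    model = BayesFactorModel(spec, Route(doc["route"]), beta, prior)
    model.clip_fraction = doc.get("clip_fraction", 0.0)
    return model
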