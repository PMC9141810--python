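"""Synthetic test-statistic ensembles with known priors.

Samples are drawn from superposition densities ``rho(r) = int rho(r|u)
pi(u) du`` by ancestral sampling: draw the noncentrality u from the prior,
then the statistic r given u.  The normal and chi-square families use exact
samplers (shifted normal; noncentral chi-square); the compact-support t and
F families use inverse-CDF sampling on a dense cumulative grid of the
hyperspherical density.

Two generators emulate common genomics designs: ``paired_t_fixture``
(paired-design microarray t-statistics, nu2 = 42 by default, i.e. 22 pairs)
and ``gwas_fixture`` (GWAS chi-square df=1 statistics from a null/non-null
mixture).  The exponential law for non-null GWAS effect sizes is a fixture
choice for testing, not an empirical claim.

All randomness flows through one ``numpy.random.Generator`` derived from an
explicit seed; no global state is touched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import noncentral_pdf
from .families import Family, FamilySpec, chi2_family, t_family

__all__ = [
    "PriorRepresentation",
    "PriorSpec",
    "SampleSet",
    "sample_noncentral",
    "sample_superposition",
    "gwas_fixture",
    "paired_t_fixture",
]

_CDF_GRID = 4096


class PriorRepresentation(str, enum.Enum):
    POINT_MASSES = "point_masses"
    DENSITY_ON_GRID = "density_on_grid"


@dataclass
class PriorSpec:
    """A known prior over the expansion variable u: weighted atoms, or a
    density tabulated on a grid (weights must be nonnegative, summing to 1)."""

    spec: FamilySpec
    representation: PriorRepresentation
    locations: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.locations = np.asarray(self.locations, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("prior weights must be nonnegative")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise ValueError("prior weights must sum to 1")
        lo, hi = self.spec.prior_domain
        if np.any(self.locations < lo) or np.any(self.locations > hi):
            raise ValueError("prior locations outside the prior domain")

    @classmethod
    def point_masses(cls, spec: FamilySpec, atoms: dict[float, float]) -> "PriorSpec":
        locs = np.array(sorted(atoms))
        return cls(spec, PriorRepresentation.POINT_MASSES,
                   locs, np.array([atoms[v] for v in locs]))

    def moment(self, n: int) -> float:
        """Analytic prior moment E_pi[u^n] (= the population beta_n)."""
        return float(np.dot(self.weights, self.locations ** n))

    def draw_u(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.locations, size=n, p=self.weights)


@dataclass
class SampleSet:
    """Statistics drawn from a known superposition density."""

    spec: FamilySpec
    values: np.ndarray
    true_u: np.ndarray
    seed: int
    prior: PriorSpec | None = None
    is_null: np.ndarray = field(default=None)

    @property
    def size(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        null = self.is_null if self.is_null is not None else (self.true_u == 0.0)
        return pd.DataFrame({"statistic": self.values,
                             "true_ro": self.true_u,
                             "is_null": null.astype(int)})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _inverse_cdf_sampler(spec: FamilySpec, u: float, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws for the compact-support t/F densities on a
    ``_CDF_GRID``-point cumulative grid with monotone interpolation."""
    lo, hi = spec.support
    eps = 1e-9
    grid = np.linspace(lo + eps, hi - eps, _CDF_GRID)
    pdf = np.asarray(noncentral_pdf(spec, grid, u))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    # strictly increasing for interpolation
    cdf = np.maximum.accumulate(cdf)
    return np.interp(rng.uniform(size=n), cdf, grid)


def sample_noncentral(spec: FamilySpec, u: float, n: int, seed) -> SampleSet:
    """Draw n statistics at fixed noncentrality u (expansion variable)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = spec.prior_domain
    if not (lo <= u <= hi) or (spec.compact and abs(u) >= 1.0):
        raise ValueError(f"noncentrality u={u} outside the prior domain")
    rng = np.random.default_rng(seed)
    values = _draw(spec, float(u), int(n), rng)
    return SampleSet(spec, values, np.full(n, float(u)), seed)


def _draw(spec: FamilySpec, u: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family is Family.NORMAL:
        return rng.normal(u, 1.0, size=n)
    if spec.family is Family.CHI2:
        lam = 2.0 * u
        if lam == 0.0:
            return stats.chi2.rvs(spec.nu1, size=n, random_state=rng)
        return stats.ncx2.rvs(spec.nu1, lam, size=n, random_state=rng)
    return _inverse_cdf_sampler(spec, u, n, rng)


def sample_superposition(prior: PriorSpec, n: int, seed) -> SampleSet:
    """Ancestral sampling from the superposition density under ``prior``."""
    rng = np.random.default_rng(seed)
    u = prior.draw_u(int(n), rng)
    values = np.empty(n, dtype=float)
    for uu in np.unique(u):
        mask = u == uu
        values[mask] = _draw(prior.spec, float(uu), int(mask.sum()), rng)
    return SampleSet(prior.spec, values, u, seed, prior=prior)


def gwas_fixture(n_snps: int, pi0: float = 0.99, effect_scale: float = 25.0,
                 seed=0) -> SampleSet:
    """GWAS-like chi-square df=1 statistics from a null/non-null mixture.

    Each SNP is null with probability ``pi0`` (central chi2_1); otherwise its
    noncentrality Lambda is exponential with mean ``effect_scale``.  The
    resulting p-value density is enriched near 0 whenever pi0 < 1.
    """
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    spec = chi2_family(1)
    rng = np.random.default_rng(seed)
    is_null = rng.uniform(size=n_snps) < pi0
    lam = np.zeros(n_snps)
    values = np.empty(n_snps)
    hit = ~is_null
    lam[hit] = rng.exponential(effect_scale, size=int(hit.sum()))
    values[is_null] = stats.chi2.rvs(1, size=int(is_null.sum()), random_state=rng)
    if hit.any():
        values[hit] = stats.ncx2.rvs(1, lam[hit], size=int(hit.sum()), random_state=rng)
    return SampleSet(spec, values, lam / 2.0, seed, is_null=is_null)


def paired_t_fixture(n_genes: int, nu2: float = 42.0,
                     prior: PriorSpec | None = None, seed=0) -> SampleSet:
    """Microarray-like paired-design t statistics on the angle support.

    ``nu2 = 42`` corresponds to 22 paired samples (b = 41/2).  The default
    prior is a symmetric three-atom mixture: 80% null, 10% at z = +-0.3.
    """
    if nu2 < 2:
        raise ValueError("nu2 must be >= 2")
    spec = t_family(nu2)
    if prior is None:
        prior = PriorSpec.point_masses(spec, {-0.3: 0.1, 0.0: 0.8, 0.3: 0.1})
    elif prior.spec.family is not Family.T:
        raise ValueError("prior must be a t-family prior")
    return sample_superposition(prior, n_genes, seed)
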