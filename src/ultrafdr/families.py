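"""Distribution families and their shared shape parameterization.

The four univariate test-statistic families (t, normal, F, chi-square) are
parameterized by hypersphere dimensions / degrees of freedom and carried
around as a single :class:`FamilySpec`.  The t and F statistics live on the
compact angle supports x = cos(theta); conversions to the conventional
t/F scales are explicit transforms in :mod:`ultrafdr.distributions`.

Shape conventions::

    t      b = (nu2 - 1) / 2       support x in (-1, 1)    u = z in (-1, 1)
    normal (no shape)              support r in R          u = delta in R
    F      a = (nu1 - 2) / 2,      support x in [0, 1)     u = z**2 in [0, 1)
           b = (nu2 - 2) / 2
    chi2   a = (nu1 - 2) / 2       support r in [0, inf)   u = Lambda/2 in [0, inf)

where u is the expansion variable of the translation-factor generating
function: z = delta / sqrt(delta**2 + nu2) for t, z = sqrt(Lambda / (Lambda
+ nu2)) for F.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Family(str, enum.Enum):
    """The four statistic families and their orthogonal-polynomial partners."""

    T = "t"            # Gegenbauer
    NORMAL = "normal"  # Hermite (probabilists')
    F = "f"            # shifted Jacobi
    CHI2 = "chi2"      # generalized Laguerre


_INF = math.inf


@dataclass(frozen=True)
class FamilySpec:
    """A statistic family with its shape parameters and domains.

    Do not construct directly; use :func:`t_family`, :func:`normal_family`,
    :func:`f_family` or :func:`chi2_family`, which validate the degrees of
    freedom and fill in the derived shapes.

    Attributes
    ----------
    family : Family
    a, b : float
        Shape parameters ``a = (nu1-2)/2`` and ``b = (nu2-1)/2`` (t) or
        ``b = (nu2-2)/2`` (F); ``nan`` where not applicable.
    nu1, nu2 : float
        Degrees of freedom (``nan`` where not applicable).
    support : tuple[float, float]
        Open/half-open interval of the random variable.
    prior_domain : tuple[float, float]
        Natural interval of the expansion variable ``u``.
    """

    family: Family
    a: float
    b: float
    nu1: float
    nu2: float
    support: tuple[float, float]
    prior_domain: tuple[float, float]

    @property
    def compact(self) -> bool:
        """Whether the random-variable support is a bounded interval."""
        return self.family in (Family.T, Family.F)

    def in_support(self, x) -> bool:
        lo, hi = self.support
        return bool(lo < x < hi) or (x == lo and self.family in (Family.F, Family.CHI2))

    def native_to_u(self, value: float) -> float:
        """Map a family-native noncentrality (delta or Lambda) to u."""
        if self.family is Family.T:
            return value / math.sqrt(value * value + self.nu2)
        if self.family is Family.NORMAL:
            return value
        if self.family is Family.F:
            if value < 0:
                raise ValueError("Lambda must be nonnegative")
            return value / (value + self.nu2)  # z**2
        if value < 0:
            raise ValueError("Lambda must be nonnegative")
        return value / 2.0

    def u_to_native(self, u: float) -> float:
        """Inverse of :meth:`native_to_u`."""
        if self.family is Family.T:
            if not -1.0 < u < 1.0:
                raise ValueError("z must lie in (-1, 1)")
            return math.sqrt(self.nu2) * u / math.sqrt(1.0 - u * u)
        if self.family is Family.NORMAL:
            return u
        if self.family is Family.F:
            if not 0.0 <= u < 1.0:
                raise ValueError("z**2 must lie in [0, 1)")
            return self.nu2 * u / (1.0 - u)
        if u < 0:
            raise ValueError("Lambda/2 must be nonnegative")
        return 2.0 * u


def t_family(nu2: float) -> FamilySpec:
    """t family on the angle support, ``b = (nu2-1)/2``; requires nu2 > 1."""
    if nu2 <= 1:
        raise ValueError(f"t family requires nu2 > 1, got {nu2}")
    return FamilySpec(Family.T, math.nan, (nu2 - 1) / 2.0, math.nan, float(nu2),
                      (-1.0, 1.0), (-1.0, 1.0))


def normal_family() -> FamilySpec:
    """Standard-normal family (unit variance, mean = noncentrality delta)."""
    return FamilySpec(Family.NORMAL, math.nan, math.nan, math.nan, math.nan,
                      (-_INF, _INF), (-_INF, _INF))


def f_family(nu1: float, nu2: float) -> FamilySpec:
    """F family on the angle support; requires nu1 > 0 and nu2 > 2."""
    a = (nu1 - 2) / 2.0
    b = (nu2 - 2) / 2.0
    if a <= -1:
        raise ValueError(f"F family requires nu1 > 0 (a > -1), got nu1={nu1}")
    if b <= 0:
        raise ValueError(f"F family requires nu2 > 2 (b > 0), got nu2={nu2}")
    return FamilySpec(Family.F, a, b, float(nu1), float(nu2), (0.0, 1.0), (0.0, 1.0))


def chi2_family(nu1: float) -> FamilySpec:
    """Chi-square family; requires nu1 > 0 (a > -1)."""
    a = (nu1 - 2) / 2.0
    if a <= -1:
        raise ValueError(f"chi2 family requires nu1 > 0 (a > -1), got nu1={nu1}")
    return FamilySpec(Family.CHI2, a, math.nan, float(nu1), math.nan,
                      (0.0, _INF), (0.0, _INF))


def spec_from_name(name: str, nu1: float | None = None, nu2: float | None = None) -> FamilySpec:
    """Build a FamilySpec from a family name and degrees of freedom."""
    fam = Family(name.lower())
    if fam is Family.T:
        if nu2 is None:
            raise ValueError("t family needs nu2")
        return t_family(nu2)
    if fam is Family.NORMAL:
        return normal_family()
    if fam is Family.F:
        if nu1 is None or nu2 is None:
            raise ValueError("F family needs nu1 and nu2")
        return f_family(nu1, nu2)
    if nu1 is None:
        raise ValueError("chi2 family needs nu1")
    return chi2_family(nu1)
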