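import math

import numpy as np
import pytest

import ultrafdr as uf


def rising(x: float, n: int) -> float:
    """Rising factorial (x)_n by direct product (test oracle, small n only)."""
    out = 1.0
    for k in range(n):
        out *= x + k
    return out


def quadrature_rule(spec, npoints=512):
    """Independent quadrature rule over the family support for test integrals."""
    fam = spec.family
    if fam is uf.Family.T:
        x, w = np.polynomial.legendre.leggauss(npoints)
        return x, w
    if fam is uf.Family.F:
        x, w = np.polynomial.legendre.leggauss(npoints)
        return 0.5 * (x + 1.0), 0.5 * w
    if fam is uf.Family.NORMAL:
        # keep the node range modest so e^{x^2/2} stays finite
        x, w = np.polynomial.hermite_e.hermegauss(min(npoints, 150))
        # hermegauss integrates against e^{-x^2/2}; divide it out, keep dr
        return x, w * np.exp(x * x / 2.0)
    from scipy.special import roots_genlaguerre
    # generalized rule against y^a e^{-y} handles the r^a factor exactly;
    # substitute r = 2y and divide the weight back out
    y, w = roots_genlaguerre(min(npoints, 150), spec.a)
    return 2.0 * y, 2.0 * w * np.exp(y) * y ** (-spec.a)


@pytest.fixture(scope="session")
def family_specs():
    """One representative spec per family (moderate shapes)."""
    return {
        "t": uf.t_family(5),            # b = 2
        "normal": uf.normal_family(),
        "f": uf.f_family(3, 8),         # a = 1/2, b = 3
        "chi2": uf.chi2_family(3),      # a = 1/2
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231104)
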