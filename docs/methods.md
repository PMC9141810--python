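# Methods

## The model

A column of test statistics r₁,…,r_N (t, z, F or χ² values with known
degrees of freedom) is treated as draws from a superposition density

    ρ(r) = ∫ ρ(r|u) π(u) du = BF(r) · w(r),

where w is the central (null) density, ρ(r|u) = T(r|u)·w(r) is the
noncentral density at effect size u, and π is the unknown prior over
effect sizes. The Bayes factor BF(r) = ρ(r)/w(r) equals the density of
p-values under the model (p being the central CDF of r), and the local
false discovery rate is fdr(p) = 1/(1+BF(p)).

The t and F statistics are carried on compact angle supports: x = cosθ
with t = √ν₂·x/√(1−x²) and F = (ν₂/ν₁)·x²/(1−x²). On these supports the
noncentral laws derived from translated uniform hypersphere densities
("ultraspherical") have translation factors that are generating functions
of orthogonal polynomials *for the weight w itself*:

- t: T(x|z) = (1−xz)/(1−2xz+z²)^(b+1) = Σ (2b+n)/(2b) C_n^(b)(x) zⁿ,
  b = (ν₂−1)/2, z = δ/√(δ²+ν₂);
- normal: T(r|δ) = e^(rδ−δ²/2) = Σ He_n(r) δⁿ/n!;
- F: T(x|z) = ∫ (1−xξz)(1−2xξz+z²)^(−a−b−2) w_t^(a)(ξ) dξ
  = Σ (a+b+1+n)/(a+b+1) F_n^(a,b)(x²) z^(2n), with
  F_n^(a,b)(y) = (−1)ⁿ (a+b+1)ₙ/(a+1)ₙ P_n^(a,b)(1−2y) a rescaled shifted
  Jacobi polynomial, a = (ν₁−2)/2, b = (ν₂−2)/2, z² = Λ/(Λ+ν₂);
- χ²: T(r|Λ) = ₀F₁(;a+1; Λr/4)·e^(−Λ/2) = Σ (−1)ⁿ/(a+1)ₙ L_n^(a)(r/2)(Λ/2)ⁿ,
  a = (ν₁−2)/2.

Under the convention that the polynomial weight is the *normalized* central
density, the squared norms are b/(b+n)·(2b)ₙ/n! (Gegenbauer), n! (Hermite),
(a+b+1)/(a+b+1+2n)·(a+b+1)ₙ(b+1)ₙ/((a+1)ₙ n!) (F) and (a+1)ₙ/n!
(Laguerre), all equal to 1 at order 0. The classical (translated-normal)
noncentral factors E(r|r₀)e^(−r₀²/2) are kept for comparison; they coincide
with the ultraspherical factors exactly for the normal and χ² families and
differ for t and F at low degrees of freedom — the symmetrized KL between
the two constructions vanishes as ν₂ → ∞ and grows with noncentrality.

Orthogonality turns density estimation into moment estimation:

    β̃ₙ = mean(Pₙ(rᵢ)) / (cₙ‖Pₙ‖²)  =  E_π[uⁿ]   (β̃₀ = 1 identically),

so the empirical Bayes-factor expansion coefficients in statistic space
*are* the prior moments in effect-size space. The data-constrained
maximal-entropy prior is the Gibbs measure π(u) ∝ exp(Σₙ λ̃ₙ uⁿ) whose dual
coefficients minimize the convex potential G(λ̃) = log Z(λ̃) − Σ λ̃ₙ β̃ₙ;
at the optimum E_π[uⁿ] = β̃ₙ (moment matching). λ̃₀ is pinned to 0: because
β̃₀ = 1 its gradient component vanishes identically and it only shifts the
log-partition.

Two routes produce BF:

- **prior route** — quadrature of the analytic T(r|u) against the fitted
  Gibbs prior. Always nonnegative; immune to the oscillatory (Gibbs-
  phenomenon) behaviour of truncated series near the compact t/F support
  endpoints. Default for t and F.
- **moment route** — the truncated sum Σ cₙ β̃ₙ Pₙ(r). Exact in
  expectation and cheapest; not sign-constrained, so negative values are
  clipped to 0 for density/fdr output and the clipped support fraction is
  reported. Default for normal and χ².

The moment route requires BF ∈ L²(w). Heavy-tailed effect laws violate
this — e.g. exponentially distributed χ² noncentralities — and the series
then oscillates over most of the support; the prior route remains stable
(see `examples/03_gwas_local_fdr.py`).

## Parameters that matter

- **order** (default 8): expansion order of both β̃ and the dual. The
  KL(empirical‖model) per order is reported in the fit diagnostics; on the
  synthetic fixtures it reaches the binning-noise floor by order ≤ 10.
  No automatic stopping rule is imposed.
- **prior domain**: the t/F effect variables are compact, (−1,1) and
  (0,1), and are used as-is. The normal and χ² domains are infinite, but a
  polynomial tilt need not be integrable there, so they are truncated at
  [−(max|r|+2), max|r|+2] for δ and [0, max r + 4] for Λ (configurable).
  The truncation only matters if real prior mass lives beyond the data
  range, which the data could not evidence anyway.
- **quadrature**: Gauss–Legendre, 512 nodes over the prior domain and 256
  over compact statistic supports; Gauss–Jacobi (160 nodes) for the inner
  F-translation integral. Node counts are arguments where they matter.
- **bins** (default 200): only used for KL reporting, never for fitting —
  β̃ estimation uses raw samples (unbiased, with standard errors from the
  sample variance of Pₙ(rᵢ)).

## Numerical choices

- Polynomials are evaluated by scipy's stable recurrences
  (`eval_gegenbauer`, `eval_hermitenorm`, `eval_jacobi`,
  `eval_genlaguerre`); the explicit hypergeometric sums appear only as
  small-n oracles in the test suite, since they lose precision at large n.
  Pochhammer symbols and norm prefactors are computed in log-Gamma space.
- The F-family translation factor's closed form is the one-dimensional
  inner-sphere integral, evaluated by a Gauss–Jacobi rule matched to the
  weight (≈1e−13 accurate for z bounded away from 1). At a = −1/2 (ν₁ = 1)
  the inner weight degenerates to half point masses at ξ = ±1 and the
  integral reduces to a two-term reflected sum, which is used directly; for
  −1 < a < −1/2 the series is summed adaptively. The generating-function
  identity (series vs closed form) is asserted in CI for all four families
  and pins every coefficient and norm formula simultaneously.
- The Gibbs potential is minimized with an exact-Hessian trust-region
  Newton method (`trust-exact`), using the analytic gradient (moment
  mismatch) and Hessian (basis covariance under the tilted measure, PSD —
  the problem is convex). The optimization runs in Legendre polynomials
  affinely mapped onto the prior domain: their near-orthogonality keeps the
  Hessian well conditioned where raw monomials fail by many orders of
  magnitude. Coefficients are converted back to the monomial dual exactly.
  Solver restarts (which reset the trust radius) handle slow tail phases.
- **Degenerate priors.** The moment vector of a k-atom prior with
  2k ≤ order+1 lies on the boundary of the moment space, where the dual
  optimum is at infinity; sampling noise can even push the estimated β̃
  slightly outside. The fit then stalls at the iteration cap with a small
  residual gradient: the returned prior is the correctly *concentrated*
  best approximation and is delivered with a logged warning rather than an
  error. A hard error is raised only for non-finite values, a gradient of
  order one (target far outside the feasible set), or a potential no better
  than the zero start.
- Out-of-support density evaluations return 0 (not an error) so binned
  boundary data cannot crash a fit; p-values are clipped to
  [1e−12, 1−1e−12] before quantile inversion; KL integrands clip densities
  at the machine floor with a warning.
- Tie-break in `fit_model`: the route defaults to PRIOR for compact
  supports and MOMENT otherwise, and can be forced either way.

## The synthetic-data generator

`synthetic` draws statistic ensembles by ancestral sampling (effect u from
a known prior, then r | u): exact shifted-normal and noncentral-χ²
samplers, and inverse-CDF sampling on a 4096-point cumulative grid for the
compact t/F supports (the sampler's KS statistic against the quadrature CDF
passes at α = 0.01 for n = 10⁵). Two fixtures emulate genomics designs:

- `paired_t_fixture`: paired-design t statistics at ν₂ = 42 (22 pairs),
  default prior 80–90% null with small symmetric effects in z;
- `gwas_fixture`: χ² df = 1 statistics, a null fraction π₀ (default 0.99)
  and exponential noncentralities (mean 25) for the rest. The exponential
  law is a testing convenience, not an empirical claim about GWAS effects.

What these fixtures deliberately omit: correlation between statistics (LD,
gene co-expression), misspecified null distributions, and estimated
degrees of freedom. Passing tests therefore demonstrate correctness of the
estimator under independent sampling from the assumed family — not
robustness to the dependence and miscalibration found in real genomics
data, where the usual empirical-null caveats apply.

Problem sizes in the test suite (n = 2×10⁵ ensembles, 200 bins, order ≤ 10)
were chosen so three-standard-error moment recovery is a sharp test while
the whole suite stays interactive.

## Limitations

- Only the four families with known generating functions are covered;
  doubly noncentral laws and arbitrary weights are out of scope.
- The moment route degrades for priors whose Bayes factor leaves L²(w)
  (heavy tails) and near compact support endpoints; use the prior route.
- fdr values carry no confidence statement; β̃ standard errors are
  reported but not propagated through the convex fit.
- The infinite-domain truncation makes extreme-tail BF values (beyond the
  data range) extrapolations of the polynomial tilt, not inferences.
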