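# ultrafdr

Empirical-Bayes modeling of test-statistic ensembles — t, normal, F, and
χ² — built on two ideas:

1. **Noncentral distributions are modular.** Every univariate noncentral
   density factors as its central density times a translation factor,
   ρ(r|r₀) = T(r|r₀)·w(r). When the noncentral laws are derived from
   translated uniform densities on unit hyperspheres ("ultraspherical"
   construction), T(r|r₀) is a *generating function* of a classical
   orthogonal-polynomial family whose weight is the central density itself:

   | family | polynomials P_n | expansion variable u |
   |---|---|---|
   | t (angle x = cosθ) | Gegenbauer C_n^(b), b = (ν₂−1)/2 | z = δ/√(δ²+ν₂) |
   | normal | Hermite He_n | δ |
   | F (angle) | shifted Jacobi F_n^(a,b), a = (ν₁−2)/2, b = (ν₂−2)/2 | z² = Λ/(Λ+ν₂) |
   | χ² | Laguerre L_n^(a)(r/2), a = (ν₁−2)/2 | Λ/2 |

   so that T(r|u) = Σₙ cₙ Pₙ(r) uⁿ with simple coefficients cₙ.

2. **Maximum-entropy priors are cheap in this basis.** Writing the
   empirical density of a statistic column as ρ(r) = BF(r)·w(r), the
   expansion coefficients β̃ₙ = mean(Pₙ(rᵢ))/(cₙ‖Pₙ‖²) equal the moments
   E_π[uⁿ] of the latent effect-size prior. The data-constrained
   maximal-entropy (Gibbs) prior π(u) ∝ exp(Σ λ̃ₙ uⁿ) follows from an
   unconstrained convex minimization of the Gibbs potential
   G(λ̃) = log Z(λ̃) − Σ λ̃ₙ β̃ₙ, whose gradient is the moment mismatch.
   The Bayes factor is then modeled either as ∫T(r|u)π(u)du (prior route)
   or as the truncated sum Σ cₙ β̃ₙ Pₙ(r) (moment route), and the local
   false discovery rate is fdr(p) = 1/(1+BF(p)).

The package is aimed at statisticians and genomicists who want local fdr
curves and effect-size priors from a single column of test statistics
(microarray/RNA-seq t statistics, GWAS χ² statistics), plus the numerics
underneath: the polynomial families under the central-density weight
convention, closed-form and series translation factors, the classical
(translated-normal) factors for comparison, and seeded synthetic ensembles
with known priors for validation.

## Worked example

Fit microarray-like paired t statistics (ν₂ = 42; 90% null genes, 10% with
an effect at z = 0.3) and recover the prior:

```python
import ultrafdr as uf

spec  = uf.t_family(42)
prior = uf.PriorSpec.point_masses(spec, {0.0: 0.9, 0.3: 0.1})
data  = uf.paired_t_fixture(200_000, nu2=42, prior=prior, seed=4)
model = uf.fit_model(data.values, spec, order=8)

print(model.beta.beta[1], model.prior.mean())
```

Running `python examples/02_maxent_prior_fit.py` prints

```
prior moments in z (estimated vs true, +- 3 SE):
  n=1: +0.02979 vs +0.03000  (3SE = 0.00121)
  n=2: +0.00906 vs +0.00900  (3SE = 0.00034)
  ...
fitted Gibbs prior: mean E[z] = 0.0298 (true 0.03)
mass near z=0:   0.895 (true 0.9)
mass near z=0.3: 0.105 (true 0.1)
```

— the estimated β̃ₙ are the prior moments (here recovered within three
standard errors), and the fitted Gibbs prior re-concentrates on the two
atoms the data were simulated from. `examples/03_gwas_local_fdr.py` runs
the GWAS analogue and prints the local fdr falling from ≈0.5 in the null
bulk to 3×10⁻⁵ at the strongest association; `examples/01_*.py` and
`examples/04_*.py` demonstrate the distribution machinery and the
tide-geometry interpretation of the spherical translation factor.

## Command line

A thin CLI wraps the same pipeline:

```bash
ultrafdr simulate --family t --nu2 42 --n 100000 \
    --atom 0:0.9 --atom 0.3:0.1 --seed 1 --out sim.tsv
ultrafdr fit sim.tsv --family t --nu2 42 --angle-scale --out-dir out/
ultrafdr fdr out/model.json --p 0.001
ultrafdr kl-compare --family t --nu2 5 --nc 0 --nc 1 --nc 3
ultrafdr tide --ratio 0.2
```

`fit` writes `model.json` (documented schema), `fdr_table.tsv` (statistic,
p, BF, fdr per record) and `diagnostics.json` (β̃ with standard errors, λ̃,
KL against the empirical density per expansion order, clipping fraction).

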