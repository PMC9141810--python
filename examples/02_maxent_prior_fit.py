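"""Maximum-entropy prior recovery from a known two-group mixture.

Simulates microarray-like paired t statistics (nu2 = 42) where 90% of genes
are null and 10% carry an effect at z = 0.3, estimates the Bayes-factor
expansion coefficients (= prior moments), fits the Gibbs prior, and reads
off the recovered effect fraction and location.
"""

import numpy as np

import ultrafdr as uf

spec = uf.t_family(42)
prior = uf.PriorSpec.point_masses(spec, {0.0: 0.9, 0.3: 0.1})
data = uf.paired_t_fixture(200_000, nu2=42, prior=prior, seed=4)

model = uf.fit_model(data.values, spec, order=8)
beta = model.beta
print("prior moments in z (estimated vs true, +- 3 SE):")
for n in range(1, 7):
    print(f"  n={n}: {beta.beta[n]:+.5f} vs {prior.moment(n):+.5f}"
          f"  (3SE = {3 * beta.se[n]:.5f})")

g = model.prior
print(f"\nfitted Gibbs prior: mean E[z] = {g.mean():.4f} (true 0.03)")
mass_null = g.masses[np.abs(g.nodes) < 0.1].sum()
mass_eff = g.masses[np.abs(g.nodes - 0.3) < 0.1].sum()
print(f"mass near z=0:   {mass_null:.3f} (true 0.9)")
print(f"mass near z=0.3: {mass_eff:.3f} (true 0.1)")
print(f"moment-match residual: {g.moment_residual:.2e}")
# The Gibbs prior is the smoothest density consistent with the estimated
# moments; it concentrates on the two atoms the data were drawn from.
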