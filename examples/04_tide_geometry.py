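"""The spherical translation factor as a tidal force field.

With the moon at distance D from a sphere of radius R (units Gm/D^2 = 1),
the horizontal tidal force at polar angle theta equals the spherical
(nu2 = 2) noncentral-t translation factor with z = R/D.  Weighted by the
spherical surface density it integrates to exactly 1, and subtracting the
unit centrifugal force shows the asymmetric near/far bulges.
"""

import numpy as np

import ultrafdr as uf

geom = uf.TideGeometry(0.2)
print(f"integrated horizontal force = {uf.integrated_horizontal_force(geom):.10f}")

theta = np.linspace(0.0, np.pi, 7)
field = uf.net_force_field(geom, theta)
print(field.to_string(index=False, float_format=lambda v: f"{v:9.5f}"))

th0 = field["net_horizontal"].iloc[0]
thpi = field["net_horizontal"].iloc[-1]
print(f"\nnear bulge {th0:+.4f} vs far bulge {thpi:+.4f}: "
      "the geometric tide is not symmetric")
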