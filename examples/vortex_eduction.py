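"""lambda_2 vortex eduction on closed-form velocity fields.

A Lamb-Oseen vortex has a sharp lambda_2 < 0 core whose radius equals the
radius of maximum swirl velocity (about 1.12 r_c); a pure shear layer has
lambda_2 = 0 everywhere (no vortex despite strong vorticity).
"""

import numpy as np
from scipy.optimize import brentq

from thromboflow import analytic_fixture, educe_vortices, lambda2

x = np.linspace(-0.8, 0.8, 200)
Gamma, r_c = 1.5, 0.2
f = analytic_fixture("lamb_oseen", {"Gamma": Gamma, "r_c": r_c}, (x, x))
lam = lambda2(f.gradient_tensor())
regions = educe_vortices(lam, threshold=-1e-6 * abs(lam.values.min()))

dx = x[1] - x[0]
r_measured = np.sqrt(regions[0].n_cells * dx**2 / np.pi)
v = lambda d: Gamma / (2 * np.pi * d) * (1 - np.exp(-(d / r_c) ** 2))
r_exact = brentq(lambda d: (v(d + 1e-7) - v(d - 1e-7)), 0.5 * r_c, 3 * r_c)

print(f"Lamb-Oseen vortex (Gamma = {Gamma} m^2/s, r_c = {r_c} m):")
print(f"  vortical regions found : {len(regions)}")
print(f"  min lambda_2           : {lam.values.min():.1f} 1/s^2")
print(f"  core radius (measured) : {r_measured:.4f} m")
print(f"  core radius (analytic) : {r_exact:.4f} m")

shear = analytic_fixture("pure_shear", {"gamma": 100.0}, (x, x))
lam_s = lambda2(shear.gradient_tensor())
print(f"\npure shear, gamma = 100 1/s: max |lambda_2| = "
      f"{abs(lam_s.values).max():.2e} 1/s^2 (no vortex)")
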