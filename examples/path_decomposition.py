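"""Decompose a SNP-phenotype correlation into direct and mediated paths.

Builds a system in which a SNP influences an end-point phenotype (think
BMI) partly through seasonal perturbations of network properties: two of
four candidate mediators truly respond to genotype.  Mediators are
screened at the 10% significance level, then the correlation r_gz is
split into a direct path and indirect paths through the retained
mediators.
"""

import numpy as np
import pandas as pd

from mnqtl.path_analysis import PathSystem, decompose, mi_correlation, select_mediators

rng = np.random.default_rng(2)
n = 127
g = ((rng.random(n) < 0.35).astype(int) + (rng.random(n) < 0.35).astype(int) - 1).astype(float)

mediators = pd.DataFrame(
    {
        "closeness_shift": 0.45 * g + rng.normal(0, 1, n),
        "pagerank_shift": 0.30 * g + rng.normal(0, 1, n),
        "betweenness_shift": rng.normal(0, 1, n),
        "eccentricity_shift": rng.normal(0, 1, n),
    }
)
z = 0.25 * g + 0.5 * mediators["closeness_shift"] + rng.normal(0, 1, n)

system = PathSystem(g, mediators, z)
chosen = select_mediators(system, alpha=0.10)
model = decompose(system, mediators=chosen)

print(f"mutual-information genotype correlation r_gz = {mi_correlation(g, z):+.3f}")
print(f"mediators retained at the 10% level: {chosen}")
print(f"\ndirect path   P(z<-g)        = {model.direct:+.3f}")
for name in chosen:
    print(f"indirect via  {name:<18} = {model.indirect[name]:+.3f} "
          f"(P(z<-y) = {model.mediator_coefficients[name]:+.3f}, "
          f"r_gy = {model.r_gy[name]:+.3f})")
print(f"check: direct + indirect      = {model.direct + model.total_indirect:+.3f} "
      f"(= r_gz = {model.r_gz:+.3f})")
print(f"R^2 = {model.r_squared:.3f}; residual path P(z<-e) = {model.residual_path:.3f}")
print(
    "\nThe decomposition identity is exact by construction; the residual path\n"
    "collects everything (other loci, environment) not routed through the\n"
    "SNP or the retained network perturbations."
)
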