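"""Reconstruct cohort interaction networks and read off their properties.

Builds a synthetic 60-host community in which the five most abundant
taxa co-vary tightly (near-tied abundances inflate the mutualism
descriptor), reconstructs the significance-filtered mutualism network,
and prints the emergent-property indices and hub report.  The denser
directed aggression network is used to illustrate the scale-free test.
"""

import numpy as np
import pandas as pd

from mnqtl.descriptors import descriptor_tensor
from mnqtl.network import build_network, centralities, detect_hubs, powerlaw_test

rng = np.random.default_rng(1)
n_hosts, n_taxa = 60, 30
hosts = [f"H{i:02d}" for i in range(n_hosts)]
taxa = [f"genus{j:02d}" for j in range(n_taxa)]

# background taxa: widely separated abundance scales
base = np.geomspace(1, 3e3, n_taxa)
X = base * rng.lognormal(0, 0.6, (n_hosts, n_taxa))
# a cooperating block at the top of the abundance range, drawn near a
# shared per-host level (near-ties -> large mutualism descriptor)
level = rng.lognormal(10, 0.4, n_hosts)
for j in range(5):
    X[:, j] = level * rng.lognormal(0, 0.08, n_hosts)

abundance = pd.DataFrame(X, index=hosts, columns=taxa)
tensor = descriptor_tensor(abundance).winsorize(0.99)

net = build_network(tensor, "mutualism", alpha=0.05, n_perm=2000, seed=0)
print(f"mutualism network: {net.n_nodes} taxa, {net.n_edges} significant edges")
print(net.edge_list().to_string(index=False))

prof = centralities(net)
print("\nper-network property indices (mean over microbes):")
print(prof.aggregate().round(4).to_string())

hubs = detect_hubs(net, abundance.mean())
print(f"\nhubs (degree > median + 1 MAD): {hubs.hubs}")
print(f"hub vs non-hub abundance t-test: t={hubs.t_statistic:.2f}, p={hubs.p_value:.3g}")

agg = build_network(tensor, "aggression", alpha=0.05, n_perm=2000, seed=0)
pl = powerlaw_test(agg, n_boot=100, seed=0)
print(f"\naggression network: {agg.n_edges} directed edges")
if pl.defined:
    print(f"power-law degree fit: exponent={pl.exponent:.2f}, "
          f"goodness-of-fit p={pl.p_value:.2f} (small p rejects scale-freeness)")
else:
    print("too few connected nodes for a power-law test")
print(
    "\nThe cooperating block forms the dense core of the mutualism network:\n"
    "its members are the hub (keystone) taxa and, being drawn at the top of\n"
    "the abundance range, they are significantly more abundant than the rest.\n"
    "In this synthetic community the aggression degrees concentrate on the\n"
    "extreme-abundance taxa, so the power-law (scale-free) fit is rejected."
)
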