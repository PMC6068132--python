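"""The improved-fixed-density (IFD) sampler and its auxiliary edge parameter.

The IFD proposal keeps the edge count pinned to its observed value by
alternating uniform deletions and insertions, while an auxiliary edge
parameter theta_L is adapted by the same signed-square rule used for the
model parameters.  On an edge-only model the adapted theta_L converges
to ln(L / (D - L + 1)) -- the logit of the observed density -- which is
exactly the Bernoulli maximum-likelihood edge parameter.
"""

import math

import numpy as np

import ergm_ee as ee

rng = np.random.default_rng(3)
g = ee.Graph(80)
for i in range(g.n):
    for j in range(i + 1, g.n):
        if rng.random() < 0.1:
            g.toggle_edge(i, j)

L, D = g.num_edges, g.num_dyads
target = math.log(L / (D - L + 1.0))
model = ee.ModelSpec([], fixed_density=True)
_, theta_L_trace, _ = ee.ifd_run(g, model, steps=400_000, rng=rng)
est = theta_L_trace[len(theta_L_trace) // 2:].mean()

print(f"observed: L={L} edges of D={D} dyads (density {L / D:.4f})")
print(f"adapted theta_L (trace average): {est:.4f}")
print(f"closed-form target ln(L/(D-L+1)): {target:.4f}")
print("agreement shows the occupancy-balance adaptation finds the MLE edge parameter")
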