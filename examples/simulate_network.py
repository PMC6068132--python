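"""Draw a network from an ERGM at fixed parameters.

Simulates a 100-node graph from an edge + alternating-triangle model by
Metropolis-Hastings and prints the realized statistics.  The positive
triangle weight makes triangles over-represented relative to a random
graph of the same density.
"""

import numpy as np

import ergm_ee as ee

model = ee.ModelSpec(
    [ee.StatisticDescriptor("edge"), ee.StatisticDescriptor("alt_triangle", lam=2.0)],
    np.array([-4.0, 0.8]),
)
g = ee.generate_network(100, model, model.theta, np.random.default_rng(0))

z = ee.statistic_vector(g, model)
a = g.adj.astype(int)
triangles = np.trace(a @ a @ a) // 6
print(f"N={g.n}, edges={g.num_edges}, density={g.density:.4f}")
print(f"statistics {model.labels}: {np.round(z, 2)}")
print(f"triangle census: {triangles}")
print(f"(a Bernoulli graph of this density would carry ~{g.density**3 * g.n**3 / 6:.0f} triangles)")
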