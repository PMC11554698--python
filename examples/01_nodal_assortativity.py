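"""Global and nodal assortativity on a small weighted network.

Builds a toy 8-node network with one hub, computes the global degree
assortativity r and its exact per-node decomposition r_i, and verifies the
identity sum_i r_i = r.
"""

import numpy as np

from assortnet import Connectome, global_assortativity, nodal_assortativity

edges = [(0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (1, 2), (3, 4), (5, 6), (6, 7)]
A = np.zeros((8, 8))
for i, j in edges:
    A[i, j] = A[j, i] = np.random.default_rng(i * 10 + j).uniform(0.5, 2.0)

net = Connectome(A, modality="structural")
r = global_assortativity(net)
vec = nodal_assortativity(net)

print(f"global assortativity r = {r:.4f}")
print("node  degree  delta_i  r_i")
deg = (np.abs(A) > 0).sum(1)
for i in range(8):
    print(f"{i:4d}  {deg[i]:6d}  {vec.extras['delta'][i]:7.3f}  {vec.values[i]:+.4f}")
print(f"sum of r_i = {vec.values.sum():.4f}  (equals r: the decomposition is exact)")
print("\nThe hub (node 0) connects to low-degree leaves, so its neighbor-degree")
print("disparity delta is large and its local assortativity r_i is the most negative:")
print("locally, this network mixes disassortatively around the hub.")
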