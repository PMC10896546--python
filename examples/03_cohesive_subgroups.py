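"""CONCOR cohesive subgroups on a network with four planted blocks.

48 nodes in four groups of 12; ties are dense within groups (p=0.6) and
sparse between (p=0.05). Depth-2 CONCOR should recover the four blocks;
the block density matrix and its alpha-image summarize between-group flow.
"""

import numpy as np

from ecolandnet import TieNetwork, concor_tree

rng = np.random.default_rng(8)
labels = np.repeat(np.arange(4), 12)
P = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
A = (rng.random((48, 48)) < P).astype(int)
np.fill_diagonal(A, 0)
net = TieNetwork(cities=[f"C{i:02d}" for i in range(48)], A=A,
                 threshold_used=0.0)

res = concor_tree(net, depth=2)
sizes = [len(res.group_members(g)) for g in range(1, res.n_groups + 1)]
print("subgroup sizes:", sizes)
print("block density matrix (row sends to column):")
print(np.round(res.density_matrix, 3))
print(f"image matrix at alpha = overall density ({res.alpha:.3f}):")
print(res.image_matrix)
print()
print("Diagonal densities ~0.6 and off-diagonal ~0.05 match the planted")
print("model; the image keeps only block pairs at least as dense as the")
print("whole network, here exactly the four within-group cells.")
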