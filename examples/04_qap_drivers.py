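"""MRQAP driver inference on a network with known planted effects.

A synthetic 47-city geography supplies attribute-difference matrices and a
contiguity matrix; ties are sampled from a logistic model with a strong
positive adjacency effect (+2) and a negative agricultural-economy
difference effect (-2). MRQAP with joint row-and-column permutations
should recover both signs with small p-values.
"""

import numpy as np

from ecolandnet import SyntheticConfig, generate_panel, generate_tie_network, mrqap_regression
from ecolandnet.gravity import TieNetwork
from ecolandnet.pipeline import build_qap_design

cfg = SyntheticConfig(seed=5, planted_beta={"adjacency": 2.0,
                                            "agri_economy_diff": -2.0})
panel, attrs, contiguity = generate_panel(cfg)
placeholder = TieNetwork(cities=panel.cities,
                         A=np.zeros((47, 47), dtype=int), threshold_used=0.0)
predictors = build_qap_design(placeholder, attrs, contiguity)
net, planted = generate_tie_network(cfg, predictors, cities=panel.cities)

result = mrqap_regression(net.A, predictors, n_perm=5000, seed=5)
print(result.table[["predictor", "r", "p_corr", "beta", "p_reg", "stars"]]
      .to_string(index=False))
print(f"\nR^2 = {result.r_squared:.3f}, adjusted R^2 = "
      f"{result.adj_r_squared:.3f}  ({result.n_permutations} permutations)")
print("planted effects:", {k: v for k, v in planted.items()
                           if not k.startswith('_')})
print()
print("The planted predictors come out signed correctly and starred;")
print("unplanted differences hover near zero with large p-values.")
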