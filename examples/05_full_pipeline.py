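"""The whole chain on a synthetic 47-city x 11-year yearbook panel.

Generates the panel, scores every city-year by per-year super-SBM with
carbon emissions as the undesirable output, builds per-year gravity
networks, and summarizes the final-year network's density, centrality,
cohesive subgroups and MRQAP drivers.
"""

from ecolandnet import PipelineConfig, SyntheticConfig, generate_panel
from ecolandnet.pipeline import run_all

panel, attrs, contiguity = generate_panel(SyntheticConfig(seed=1))
config = PipelineConfig(seed=1, n_permutations=2000)
result = run_all(panel, attrs, contiguity, config)

print("province x year mean efficiency (last rows):")
print(result.report.tail(3))
year = max(result.networks)
d = result.density[year]
print(f"\n{year} network: m={d.m} ties, density={d.density:.3f}")
print(f"share of cities in the top two grades: {result.top_band_share}%")
print("subgroup sizes:",
      [len(result.concor.group_members(g))
       for g in range(1, result.concor.n_groups + 1)])
print(f"MRQAP R^2 = {result.qap.r_squared:.3f}")
print(result.qap.table[["predictor", "beta", "p_reg", "stars"]]
      .to_string(index=False))
print()
print("Provinces were generated with a productivity gradient, so their")
print("mean efficiencies separate; the gravity network sits near the")
print("~0.2-density regime and CONCOR finds four cohesive subgroups.")
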