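# ecolandnet

Spatial-association network analysis of cultivated-land-use eco-efficiency.

City-level agricultural panels (inputs: crop sown area, primary-industry
labor, machinery power, chemical fertilizer; outputs: grain output and gross
agricultural output value; carbon emissions as the undesirable output) are
scored by slacks-based-measure (SBM) DEA with super-efficiency for frontier
cities; the scores become the masses of a modified gravity model whose
thresholded strengths define a directed spatial network; the network is
characterized by density, Freeman centralities and CONCOR cohesive
subgroups; and the drivers of tie formation are tested by QAP/MRQAP
permutation inference. The package is aimed at regional-agriculture and
land-systems researchers who want this whole chain as tested, scriptable
Python instead of a relay of MaxDEA, UCINET and spreadsheet steps.

## The model chain

**Efficiency.** Each city-year is a DMU with inputs x, desirable outputs
y^g and carbon emissions y^b (a coefficient-weighted sum over carbon
sources). The SBM score is

    rho* = min [1 - (1/m) Σ s_i^- / x_i0] / [1 + 1/(s1+s2) (Σ s_r^g/y_r0^g + Σ s_t^b/y_t0^b)]
    s.t. x0 = Xλ + s^-,  y0^g = Y^g λ - s^g,  y0^b = Y^b λ + s^b,  λ, s ≥ 0

solved as an LP after the Charnes–Cooper substitution; rho ∈ (0,1] and
equals 1 exactly on the frontier. Frontier cities are re-scored by
super-efficiency δ ≥ 1 against the frontier formed without them (the
undesirable output moving direction-wise like an input). The final score
P (= rho or δ) is banded: high (P≥1), relatively high [0.8,1), medium
[0.6,0.8), low [0.4,0.6), lowest (<0.4).

**Network.** With masses M_i = P_i and great-circle distances D_ij,

    S_ij = K_ij · M_i M_j / D_ij^b,   K_ij = M_i/(M_i+M_j),   b = 2

gives a directed strength matrix (K_ij + K_ji = 1); ties are strengths
strictly above the mean off-diagonal strength. Density is m/n(n−1);
degree, closeness and betweenness follow Freeman's normalized definitions
on the symmetrized network; CONCOR (iterated correlation convergence, depth
2) yields four cohesive subgroups with a block-density matrix and its
binary image under the α-density criterion (α = overall density).

**Inference.** MRQAP regresses the vectorized off-diagonal tie matrix on
six attribute-difference matrices and spatial adjacency, with coefficient
p-values from joint row-and-column permutations (Y-permutation by default,
double semi-partialing available).

## Worked example

`examples/05_full_pipeline.py` generates a synthetic 47-city × 11-year
yearbook panel (four provinces with a planted productivity gradient) and
runs the whole chain:

```
province x year mean efficiency (last rows):
province     P1     P2     P3     P4  average
year
2019      0.932  0.676  0.566  0.505    0.670
2020      0.921  0.800  0.533  0.482    0.684
Average   0.941  0.729  0.571  0.501    0.686

2020 network: m=503 ties, density=0.233
share of cities in the top two grades: 25.5%
subgroup sizes: [15, 13, 9, 10]
MRQAP R^2 = 0.322
                predictor      beta    p_reg stars
        agri_economy_diff -0.283410 0.596702
        urbanization_diff -0.331055 0.314343
        rural_income_diff -0.000099 0.000500   ***
fertilizer_intensity_diff -0.080851 0.529235
       mechanization_diff  0.009716 0.555222
          population_diff -0.000652 0.358821
                adjacency  0.741847 0.000500   ***
```

The province columns separate according to the planted gradient (P1 most
productive); the density says 23.3% of possible directed ties are realized;
the starred rows say contiguous city pairs and pairs with similar rural
incomes tie significantly more often, at p-values from 2000 label
permutations. The other examples exercise one capability each: efficiency
scoring, network construction, subgroups, QAP drivers.

A thin CLI mirrors the stages on CSV workspaces:

```bash
ecolandnet simulate ws --config config.yaml   # write a synthetic workspace
ecolandnet run-all  ws --config config.yaml   # panel -> scores -> network -> QAP
```

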