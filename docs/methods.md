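# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic generator does and does not
emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Panel model and validation

A panel is a complete city × year rectangle of yearbook indicators (units:
sown area 10³ ha, labor 10⁴ persons, machinery 10⁴ kW, fertilizer 10⁴ t,
grain 10⁴ t, output value 10⁸ yuan). Validation rejects zero or negative
values for every DEA-facing field rather than imputing: the SBM objective
divides by the evaluated unit's own inputs and outputs, so a zero is not a
small number but an undefined program, and silent imputation would corrupt
scores. City order in the panel file is canonical for every downstream
matrix; matrix files carry city-id headers on both axes so misalignment is
detected, not guessed.

Report aggregation follows the convention of provincial yearbook summaries:
the per-year "average" is the unweighted mean of the provincial means (not
of all cities), and the overall row is the mean over years. Efficiency is
printed at 3 decimals and shares at 1, matching the conventions of the
reports this pipeline emulates; tests compare unrounded aggregates so print
rounding cannot alias real errors.

## Carbon accounting

Emissions per city-year are E = Σ_k f_k q_k with per-source factors f_k in
kg C per source unit and an explicit output-scale column converting to
10⁴ t. The shipped six-source default table (fertilizer 0.8956 kg/kg,
pesticide 4.9341 kg/kg, plastic film 5.18 kg/kg, diesel 0.5927 kg/kg,
plowing 312.6 kg/km², irrigation 266.48 kg/ha) follows the synthesis
coefficients common in the Chinese agricultural carbon-accounting
literature. They are configuration, not ground truth: any source set and
factor table can be supplied, and validation demands a factor for every
source present in the panel.

## SBM efficiency with an undesirable output

The SBM program and its Charnes–Cooper linearization are in the module
docstring of `ecolandnet.dea`. Choices:

- **Returns to scale**: constant (CRS) by default — the default of the DEA
  software lineage this field uses — with variable returns (Σλ=1) as an
  option. VRS super-efficiency can be infeasible; that surfaces as a
  `DeaError` with the solver status, never a patched score.
- **Frontier scope**: per-year frontiers by default (annual cross-sections
  are the reporting unit); a pooled all-years frontier is available for
  intertemporal comparability.
- **Super-efficiency variant**: the undesirable output moves
  direction-wise like an input — the worsened point may raise bads — and
  enters the objective numerator averaged with the inputs over m+s2 terms,
  against the average retention of goods in the denominator. This is one of
  several published variants; it is recorded in the score metadata
  (`bad_direction`). Under it, a unit that halves its only input relative
  to its single peer at equal outputs scores δ = 1.5 (numerator (2+1)/2
  over denominator 1), which the test suite pins both analytically and
  against an independent nonlinear-fraction oracle.
- **Numerics**: HiGHS with primal/dual feasibility 1e-9; rho within 1e-7
  of 1 counts as efficient (the tie rule that triggers super-efficiency).
  Both programs are ratios of affine functions over polyhedra, so the LP
  optimum is global; alternate optima in λ are accepted — only the optimal
  objective and slacks are contractual. Units invariance (rescaling any
  single column for all DMUs) holds to better than 1e-9 and is tested.

## Gravity network

S_ij = K_ij M_i M_j / D_ij^b with K_ij = M_i/(M_i+M_j) and b = 2 (the
conventional distance-attenuation exponent; configurable). Distances are
great-circle on a sphere of radius 6371.0088 km; a user-supplied distance
matrix can override (projected distances are not reproducible without the
projection). The tie threshold is the mean of all off-diagonal strengths,
with strict ">" so ties at exactly the mean are 0; a row-mean variant is
provided because it is common in this literature. Per-year networks are
built from that year's scores; the final year is the default analysis
network. Binarization is invariant under common rescaling of all masses or
all distances, since threshold and strengths co-scale — a tested property.

## Centralities

The standard Freeman definitions: normalized degree deg/(n−1) on the
symmetrized network (a tie in either direction connects a pair; in/out
variants exposed), Brandes betweenness over unordered pairs normalized by
(n−1)(n−2)/2, and closeness (n−1)/farness with unreachable distances set
to n (configurable; the convention matters only on disconnected networks).
All three are verified against an independent graph library to 1e-10 on
random graphs, and betweenness additionally against brute-force shortest-
path enumeration on small graphs. Report ranks break ties lexicographically
by city id so output is deterministic; values are emitted both as fractions
and percentages because reporting scales vary across the field's software.

## CONCOR subgroups

Profiles concatenate a node's tie row and column (send and receive);
pairwise correlations drop the two positions belonging to the pair itself
(self and mutual ties), the standard treatment. The correlation matrix is
iterated (corrcoef of its own rows) until every off-diagonal entry is
within 1e-6 of ±1 (maximum 200 iterations), and the sign pattern gives the
bipartition; recursion to depth 2 yields four subgroups. Zero-variance
profiles (isolates) are assigned to the block of their most-correlated
non-degenerate node, else to the larger block, with a warning.

One deliberate refinement: the sign convergence optimizes a global
contrast and can strand an individual node on the wrong side even when its
initial profile correlations clearly favor the other block (on planted
4-block networks the stray's mean initial correlation with its own block
can be +0.25 against negatives elsewhere and still converge to the wrong
sign). Each split therefore ends with a deterministic consistency pass —
move a node while its mean initial-profile correlation with the other
block exceeds that with its own — and the depth-2 leaves get the same pass
across all four groups. On stochastic 4-block networks (n=48, p_in=0.6,
p_out=0.05) this lifts exact recovery from ~81/100 to ~96/100 seeds; on
the same benchmark the leaf pass never overturned a partition the split
passes already had right. Both passes can be disabled (`refine=False`,
`polish=False`).

Block densities divide realized by possible ties (n_g(n_g−1) on the
diagonal; singleton diagonal cells are 0); their size-weighted average
equals overall density exactly, which the tests assert to 1e-12. The image
matrix marks block pairs with density ≥ α, α defaulting to the overall
density.

## QAP / MRQAP

Statistics use vectorized off-diagonal entries only. QAP correlation
permutes node labels of one matrix (rows and columns jointly), preserving
dyadic dependence; MRQAP fits OLS and takes coefficient nulls from
Y-permutation by default — matching the permutation scheme this field's
software describes — with Dekker's double semi-partialing as the
robust-under-collinearity alternative. P-values use the add-one convention
(never exactly zero), both one- and two-tailed are reported, and stars
follow the p<0.01 / p<0.05 / p<0.1 convention. Exactly collinear
predictors and zero-variance matrices are errors, not warnings. Given
(seed, n_perm, method) every p-value is bit-for-bit reproducible. Type-I
calibration under independence and sign recovery of planted effects are
part of the test suite (rejection rate within [0.03, 0.07] at α=0.05;
|β|=2 planted effects recovered with p<0.05 in ≥80% of runs at n=47).

## Synthetic yearbook generator

The generator emulates the *statistical structure* the analysis assumes,
not any real region: log-normal city sizes (σ=0.4); inputs proportional to
size with multiplicative log-normal noise (CV 0.15 by default); outputs
carrying per-province productivity multipliers (default 1.35/1.15/0.95/
0.85 across four provinces, giving the between-province efficiency spread
the analysis is meant to resolve) plus 2%/year common productivity growth
so mean efficiency rises over the window; carbon sources proportional to
fertilizer, machinery and sown area; coordinates on a jittered grid whose
4-neighborhood is the contiguity list, keeping distance and adjacency
internally consistent. With noise set to 0, higher-multiplier provinces
dominate exactly, which pins the generator-to-DEA contract in a test.

Planted tie networks draw from logistic(β₀ + Σ β_k Z_k) on off-diagonal-
standardized predictors, default effects: adjacency +2, agricultural-
economy and mechanization differences −1. The intercept is solved by
bisection so the expected density is 0.19 — the density regime the method
is meant to operate in — rather than hand-picked.

What passing tests on generated data do **not** show: real yearbook data
have measurement error, administrative boundary changes, genuine spatial
autocorrelation in attributes, and non-grid geography; recovery rates and
calibration here certify the algorithms, not the field data.

## Problem sizes and determinism

Default experiment sizes (47 cities × 11 years; 100-seed recovery and
oracle sweeps; 500-simulation calibration at 999 permutations; 50-run
power checks at 5000 permutations) were chosen as the package's standard
verification battery; the full suite runs in well under two minutes on one
CPU. All randomness flows from explicit seeds; `run-all` on a fixed seed
reproduces every output file byte-identically, which the CLI tests assert.

## Known limitations

- No Malmquist decomposition, window or bootstrap DEA; no weighted-network
  analysis of the raw strengths; no ERGM/logistic tie models; no
  cartography — all outside scope.
- CONCOR is a heuristic: on weakly separated block structure the depth-2
  partition is not guaranteed meaningful, and tiny blocks (≤3 nodes) that
  cannot split are returned as-is.
- Super-efficiency variants differ across the literature; scores above 1
  are comparable only within the variant recorded in the metadata.
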