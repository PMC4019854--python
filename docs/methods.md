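# Methods

## Density convention and thresholding

Density of an undirected binary graph is taken throughout as
D(G) = 2‖E‖ / (‖N‖(‖N‖−1)), i.e. node pairs are counted as ordered, so a
complete graph has density 1. The same factor-2 convention is applied
consistently to the per-node clustering coefficient
(C_i = 2e_i / (k_i(k_i−1)), with e_i the edge count among i's neighbors)
and to the rich-club coefficient
(R(G, k) = 2‖E(G, k)‖ / (‖N(G, k)‖(‖N(G, k)‖−1))), so all three lie in
[0, 1] and R(G, 0) equals the graph density exactly.

Constant-density thresholding keeps the top-weighted edges until the edge
count ⌊d·N(N−1)/2 + 0.5⌋ (round half up) is reached, then sets surviving
weights to 1. Edge selection uses the total order *weight descending, then
(i, j) index pair ascending*. Two consequences matter and are tested:
thresholding is deterministic under tied weights, and the selected edge
sets are nested across increasing densities, which makes every
non-decreasing metric curve (global efficiency, largest-component size)
genuinely monotone rather than monotone-up-to-tie-noise. Zero-weight pairs
are never selectable; a target density requiring more edges than the
matrix has positive entries raises an error naming the achievable maximum.

## Metrics and their degenerate cases

All seven metrics operate on unweighted undirected graphs. Shortest paths
are hop counts from breadth-first search (via `scipy.sparse.csgraph`);
connected components likewise. Choices at the degenerate margins:

- Clustering contributes C_i = 0 for nodes of degree < 2 (vanishing
  denominator), the common binary-graph convention.
- Characteristic path length is defined only within a connected graph, so
  the largest connected component is extracted first (ties between
  equal-sized components break toward the one containing the smallest node
  index); an edgeless graph is an error, not a value.
- Global efficiency treats disconnected pairs as contributing 1/∞ = 0 and
  needs no component extraction.
- Local efficiency averages, over all N nodes, the global efficiency of
  the subgraph induced on each node's neighbors; nodes with fewer than two
  neighbors contribute 0. Of the two readings in circulation ("remove node
  i" vs. "the neighbors of i"), the neighbor-induced subgraph is the one
  that matches the fault-tolerance interpretation and the original
  efficiency literature, and is what networkx implements; it is the only
  form offered here.
- Assortativity returns a typed undefined value (`None`) when its
  denominator is zero — every edge endpoint has the same degree, e.g. any
  regular graph — rather than a NaN that would silently propagate.
- Rich club is undefined when fewer than two nodes reach degree k.

Curve code records undefined points as NaN with an explicit `defined`
flag; they are carried, never interpolated, and downstream stages
(ICC, area integration) restrict themselves to defined points.

## Dice, ICC and category bands

Edge Dice is 2‖E(a)∩E(b)‖/(‖E(a)‖+‖E(b)‖) over graphs sharing a node
ordering; two empty edge sets count as identical (Dice 1). Intra-subject
means average each subject's session pair; inter-subject means average all
cross-subject pairs under all four session combinations — the pairing
scheme is a package choice and is stated rather than inferred.

The ICC uses the one-way random-effects ANOVA method-of-moments
estimator: with n subjects and k sessions, σ̂²_bs = max(0, (MSB−MSW)/k)
and ICC = σ̂²_bs/(σ̂²_bs + MSW), equal to max(0, (MSB−MSW)/(MSB+(k−1)MSW)).
The unclamped value is reported alongside for transparency. When
MSB + MSW < 1e−10 the estimate is flagged invalid instead of reported
(the ratio is unstable without variance). Agreement bands: < 0.2 poor,
≤ 0.40 fair, ≤ 0.60 moderate, ≤ 0.80 strong, > 0.8 near-perfect; values
in the printed gap (0.2, 0.21) are assigned to fair.

At n = 200 subjects and k = 2 the estimator's sampling SD is
approximately (1−ρ)(1+ρ)·√(2/(2(n−1))) ≈ 0.05–0.07 for mid-range ρ, so
individual estimates scatter by several hundredths around the truth; the
tests assert unbiasedness and SD-scaled error bounds accordingly.

## Permutation test

The statistic is the trapezoidal integral of |mean curve A − mean curve B|
over the subgrid where every input curve is defined (that subgrid does not
change under permutation). Labels are permuted without replacement
preserving group sizes; p = x/i with x counting permuted areas **≥** the
observed one. Counting ties as extreme keeps p ∈ (0, 1] and makes two
identical groups yield p = 1 instead of 0; it is the conservative standard
convention. Permutation is at the curve level (each subject × session
curve carries its group label); a paired within-subject scheme would be an
alternative for designs where the same subjects appear in every group, but
is not implemented. Default i = 10000.

## Synthetic cohort generator

The generator stands in for everything upstream of the connectivity
matrix (acquisition, labeling, tractography). Per group, a population
backbone on N nodes is drawn once: nodes split into `n_modules` contiguous
modules, a pair connects with probability p_in within and p_out between
modules, and each present edge gets expected count `weight_scale · u`,
u ~ log-normal(0, 1). Subject s perturbs each backbone edge's log-rate by
b ~ N(0, σ²_between); session t adds e ~ N(0, σ²_within); the observed
count is Poisson at the resulting rate (multiplicative biological
variability over nonnegative integer counts). A deterministic mode emits
the rates themselves so that exact invariants (e.g. intra-subject
Dice = 1 when σ_within = 0) are testable.

Defaults — 78 nodes (approximating a cortical + deep-gray parcellation),
21 subjects × 2 sessions, 6 modules, p_in = 0.7, p_out = 0.15,
weight_scale = 30, σ_between = 0.4, σ_within = 0.15 — were chosen once to
put maximal densities near 0.2–0.3 and within-subject noise well below
between-subject variability, the regime a scan-rescan study of healthy
controls sits in. A group multiplies p_in by its `group_effect`,
injecting a topological (within-module density) group difference.

What the generator does **not** emulate: spatially correlated tractography
failure modes, distance-dependent streamline loss, label-boundary noise,
or heavy-tailed count distributions beyond the log-normal mixing. Passing
tests therefore show the *statistical machinery* behaves correctly under a
known generative model, not that any particular acquisition pipeline is
reliable.

## Pipeline and problem sizes

`run_pipeline` evaluates, on the highest density grid common to the whole
dataset (default step 0.01): six metric-vs-density curves per
subject × session, a rich-club-vs-k curve at a fixed density (default
0.15; the common-maximum density is selectable), Dice summaries and ICC
curves per group, and permutation tests for every group pair on every
metric curve plus the per-subject intra-session Dice curves. All outputs
are tidy delimited tables; a given seed reproduces them byte for byte.

The test suite and the acceptance script run everything at sizes chosen
for quick, deterministic feedback: oracle equivalence on 200 graphs of
≤ 10 nodes; thresholding contracts on 100 random matrices; calibration on
500 simulated datasets × 200 permutation iterations; power and cohort
summaries on the default 21 × 2 × 2-group design with reduced iteration
counts where the full i = 10000 adds nothing but wall time. The measured
type-I error sits near the nominal 0.05 and power against the default
group effect (p_in multiplier 1.5) is ~1.0.

## Known limitations

- The ICC is the one-way absolute-agreement form only; two-way and
  consistency variants, and confidence intervals, are out of scope.
- Weighted or directed metric variants are not provided.
- Curves are compared raw (no basis expansion or smoothing); results at a
  given density step are sensitive to the grid choice, which is therefore
  an explicit, recorded parameter.
- Inter-subject Dice pairing and curve-level permutation are stated
  package choices among defensible alternatives.
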