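# Methods

## The random-walk model

A weighted undirected network with nonnegative connectivity matrix `C`
(zero diagonal, symmetric) is interpreted as a stationary Markov chain: a
walker at node *i* steps to *j* with probability `P_ij = C_ij / C_i`,
`C_i = Σ_j C_ij`. Because the graph is undirected the chain is
reversible, and its stationary distribution is available in closed form,
`μ_i = C_i / C_T` with `C_T = Σ_ij C_ij` (each undirected edge counted
twice). No eigenvector computation is performed or needed; the package
therefore does not support genuinely directed chains — directed or
triangular input must be symmetrized first (`symmetrize` copies the upper
triangle below the diagonal and zeroes the diagonal).

Assumptions inherited from the model: the next step depends only on the
current node (one-step Markov), weights are nonnegative (negative
functional couplings must be thresholded or clipped away before
analysis; the reader exposes a `clip_negative` flag), and self-loops are
excluded. Multiplying `C` by any positive constant changes neither `P`
nor `μ`, so measures are invariant to overall connectivity scale.

Isolated nodes (zero strength) are kept in the model with `μ_i = 0` and
an all-zero transition row: sparse synthetic networks genuinely contain
them, and dropping them would silently change `n`. Their per-node
measures are undefined and reported as NaN in memory and `NA` in files,
never as 0 or infinity, so downstream tables cannot mix conventions.

## Global measures

All logarithms are base 2; all outputs are bits; `0·log 0 = 0`
throughout (implemented by masking zero terms, so no NaN arithmetic
occurs). With `h = H(Xt+1|Xt) = −Σ_i μ_i Σ_j P_ij log2 P_ij`:

- entropy `H(μ)`, in `[0, log2 n]`;
- mutual information `MI = H(μ) − h`, the excess entropy of the chain;
- erasure mutual information `EMI = H(μ) − H(Xt|Xt−1,Xt+1)`.

The context conditional entropy is defined over the triple joint
`p(j,i,k) = μ_j P_ji P_ik` (past, present, future). Rather than
materializing the `n³` array, the implementation uses the exact
reduction

    H(Xt|Xt−1,Xt+1) = 2h + Σ_jk μ_j Q_jk log2 Q_jk,   Q = P·P,

obtained by summing the `log2 P_ji` and `log2 P_ik` factors over their
free indices (row stochasticity and stationarity collapse each to `h`).
This costs one matrix product (`O(n³)` flops, `O(n²)` memory). A
brute-force path that does materialize the full triple joint and applies
the defining sums term by term lives in the test suite
(`tests/oracles.py`); the two agree to 1e-9 on randomized graphs.

Tiny negative results from floating-point cancellation (the ordering
`0 ≤ MI ≤ EMI ≤ H` is exact in real arithmetic) are clamped to 0 when
below 1e-9 in magnitude; anything larger raises, since it can only mean
an internal inconsistency.

## Local measures

Each global measure is the `μ`-weighted mean of its per-node
decomposition, and these identities (checked to 1e-9 in the tests) are
the primary correctness arbiter:

- `E_i = −log2 μ_i`, with `Σ μ_i E_i = H`;
- `I1_i = Σ_j P_ij log2(P_ij/μ_j)` (KL of row *i* from `μ`), `Σ μ_i I1_i = MI`;
- `I2_i = H(μ) + Σ_j P_ij log2 P_ij`, `Σ μ_i I2_i = MI`;
- `I1e_i = Σ_jk p(j,k|i) log2( p(j,k|i) / p(j,k) )`, `Σ μ_i I1e_i = EMI`.

For the erasure surprise the backward step distribution follows from
Bayes' rule, `p(Xt−1=j|Xt=i) = μ_j P_ji / μ_i`, which by detailed
balance equals the forward row `P_ij`; hence `p(j,k|i) = P_ij P_ik`
against the marginal `p(j,k) = μ_j Q_jk`. Pairs with `Q_jk = 0` have
zero conditional probability and contribute nothing. The computation
loops over the present node with an outer product per node (`O(n²)` each,
`O(n³)` total) — adequate far beyond the network sizes used here.

## Classical measures and fits

Strength is the row sum of `C` (bit-identical to the model's strengths).
Eccentricity is the maximal shortest-path distance per node with edge
length `1/weight`, the standard connectivity-to-length inversion in this
literature; a flag switches to unit lengths (binarized), since either
convention is defensible and sources rarely state which they used.
Nodes of disconnected graphs get NaN. Weighted clustering uses the
geometric-mean-of-triangle-weights (Onnela) formulation with weights
normalized by the maximum — the weighted undirected variant of the
common toolbox implementations — via networkx; shortest paths come from
scipy's Dijkstra.

`fit_log_curve` fits `y = a + b·log2 x` by least squares and reports
`R² = 1 − SS_res/SS_tot`. Pairs with NaN or `x ≤ 0` are dropped; fewer
than 3 surviving points is an error; constant `y` returns `R² = 0` by
convention (no variance to explain). Because
`E_i = log2 C_T − log2 strength_i` exactly, the E-vs-strength fit returns
`R² = 1`, `b = −1`, `a = log2 C_T` on any connected graph — a built-in
self-check. In `correlate_measures`, a single unfittable pair (e.g.
clustering on a triangle-free graph, where every abscissa is 0) yields a
NaN row rather than aborting the whole report.

## Synthetic networks

The four families produce a symmetric zero-diagonal matrix with exactly
`m` nonzero upper-triangle entries; requested `m` above the complete
graph is clamped (the canonical edge grids overshoot deliberately).
Exact procedures, fixed here since common toolbox internals are not
normative:

- random — `m` distinct off-diagonal pairs sampled uniformly;
- lattice — off-diagonal bands `|i−j| = k`, `k = 1, 2, …`, filled in
  increasing `k` without wraparound; the partial last band is filled in
  index order. End nodes therefore have fewer connections (boundary
  effect, visible as the entropy dip of dense lattices);
- ring lattice — the same band filling on ring distance
  `min(|i−j|, n−|i−j|)`, wrapping around, giving a near-regular graph
  (degree `2k` exactly when `m = k·n`);
- small-world — nodes are partitioned into contiguous modules of
  `cluster_size` nodes (`cluster_size` counts nodes per module; the last
  module may be smaller), each module fully connected, then uniformly
  random inter-module edges are added up to `m`; if `m` is below the
  intra-module total, intra-module edges are instead sampled uniformly.

Weights are drawn i.i.d. uniform on the open interval (0, 1) after the
topology, so edge presence and positive weight coincide; the same spec
and seed reproduce the matrix bit for bit (`numpy.random.default_rng`).

What the generators emulate — and what they do not. They reproduce the
study conditions used to characterize the measures: 128/256-node edge
sweeps (step 128 up to 8192 edges) and a node sweep (32–512 nodes at
density 0.4), with 10 replicates per grid point by default (matching the
per-group sample size of the reference box-plot experiments). They do
not emulate real connectomes: empirical weight distributions are heavy
tailed rather than uniform, real networks have hubs, hemispheric
symmetry and distance-dependent wiring, and ICA-derived functional
matrices contain thresholding artefacts. Passing sweep tests therefore
demonstrates correct measure behaviour under controlled topologies, not
claims about any particular human dataset.

## Numerical and design choices

- Tolerances: 1e-12 absolute for model invariants (row sums,
  normalization, detailed balance); 1e-9 for measure identities and
  oracle agreement, reflecting accumulation over `O(n³)` terms.
- Degenerate inputs: an empty graph (no edges) is an error; a single
  edge is the smallest valid model.
- Node indexing is 1-based in all user-facing files (default labels
  "1"…"n") and 0-based internally; the file reader/writer is the only
  boundary.
- Reports: density is rounded to 4 decimals in metadata; tables carry 12
  significant digits so a round-trip reproduces values to printed
  precision. Writers go through a temp-file-and-rename so failed runs
  leave no partial output. Max/min nodes in the JSON summary list all
  tied nodes.
- Problem sizes in the test suite: oracle comparisons run at `n ≤ 8`
  (where `n³` enumeration is exact and fast), identity checks at
  `n ≤ 64` over hundreds of random graphs, and the sweep trend checks use
  the full 64-point edge grid at `n = 128` with 5 replicates and a
  node grid to `n = 512` — together they complete in well under a minute.
  Trend assertions are made on replicate-averaged curves at spaced grid
  points, because adjacent-point differences near the complete graph are
  of the same order as weight noise.

## Known limitations

- No directed-chain support (the closed-form `μ` requires reversibility).
- Erasure measures are the one-step Markov forms; general-process
  erasure/excess entropy over longer contexts is out of scope.
- `correlate_measures` fits only the logarithmic family used in the
  comparison analyses; it is not a general model-selection tool.
- Memory is `O(n²)` dense; matrices beyond a few thousand nodes would
  want a sparse implementation.
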