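# Methods

## Model

A probabilistic network 𝒢 = (V, E, p) is an undirected simple graph whose
edges carry independent existence probabilities p : E → (0, 1].  Probability
0 is excluded by construction: an edge a user believes absent is simply not
listed, and rejecting p = 0 loudly avoids silently changing the semantics of
an input file.  Self-loops are rejected because both modularity forms used
here are defined for simple graphs.  Under possible-world semantics 𝒢 is a
generative model for the 2^m edge subsets ("worlds"), with the
independent-edge product law for each world's probability.

A clustering is a *given*, total assignment of nodes to community labels.
The package computes the expected modularity E(Q) of that clustering; it
never searches for one (community detection / modularity optimisation is a
different problem and out of scope).

Modularity of a deterministic world is computed in two algebraically
equivalent forms: the adjacency form (1/2M)Σ_ij (A_ij − k_i k_j/2M)δ(x_i,x_j)
and the community form Σ_c [x_c/m − ((2x_c + y_c)/2m)²], where x_c and y_c
count the community's present within and boundary edges.  Both are
implemented independently and cross-checked (and checked against networkx)
so that either can serve as an oracle for the other.

**Empty-world convention.**  Both forms are 0/0 when a world has no edges;
the package defines Q(∅) := 0 everywhere — in the brute-force oracle, in the
(0,0,0) partition cell, and in sampling.  Any single shared value keeps the
methods mutually consistent; 0 is the choice that makes E(Q) continuous as
all probabilities approach 0.

## Exact computation

The brute-force oracle enumerates worlds as bitmasks over the canonical
(lexicographically sorted) edge order.  World probabilities and
per-community counts are built by array doubling — appending one edge at a
time and duplicating the arrays for its absent/present branch — which gives
exact products and exact integer counts, vectorised, in the same
deterministic order a per-world loop would visit.  Enumeration refuses
networks above a cap (default 25 edges, ~33M worlds).

The partition algorithm groups worlds per community by the triple
(x, y, z) of present within/boundary/outside edge counts.  The community
term is constant on each cell; the cell probability is the product of three
Poisson-binomial factors because the three edge sets are disjoint.  Three
pmf engines implement that factor:

* **enumeration** — the literal subset-sum definition, vectorised by the
  same array-doubling trick; guarded at 20 trials;
* **convolution** — the exact O(T²) dynamic-programming recurrence, used as
  the internal cross-check;
* **DFT** — the closed form pmf[k] = 1/(T+1) Σ_l C^{−lk} ∏_i (1+(C^l−1)p_i)
  with C = exp(2πi/(T+1)).  The roots-of-unity products are accumulated in
  complex double precision per l (O(T²)); the final sum over l for all k at
  once is the length-(T+1) DFT of those products, evaluated with `np.fft.fft`
  (the identical closed form, computed in O(T log T) instead of O(T²)).

PWP uses the enumeration engine (a faithful mid-fidelity reference, refused
when any trisection part exceeds 20 edges); FPWP uses the DFT engine.  Both
iterate communities in sorted label order, then x, with the (y, z) grid of
each x-slice evaluated by numpy broadcasting; slice sums and per-community
terms are pooled with `math.fsum` so accumulation error stays far below the
1e−9/1e−8 tolerances the tests assert.  Tiny negative DFT pmf entries
(|·| ≤ 1e−8) are clamped to zero and the pmf renormalised; a larger residual
raises rather than warns.  The number of cells visited,
Σ_c (T_x+1)(T_y+1)(T_z+1), is reported in the diagnostics and depends only
on topology and clustering — never on the probabilities.

A deliberate limitation: the per-community cells give exact *marginals*, and
hence the exact expectation, but not the joint law of total Q — boundary
edge sets of different communities overlap, so the joint distribution is not
determined by these marginals.  The full distribution of Q is available only
from the brute-force oracle (or approximately from sampling).

## Estimators

**Sampling** draws whole worlds (each edge kept independently with its
probability) and averages their modularity — the plain possible-world Monte
Carlo estimator, which is unbiased for E(Q).  All randomness flows through
`numpy.random.default_rng(seed)`; sample t consumes uniforms
[t·m, (t+1)·m) of the stream in canonical edge order, so batched runs and
single-world draws with the same seed see identical worlds, and distinct
seeds give independent streams.  A time-budgeted variant draws in chunks
(first chunk of size 1 so tiny budgets still return an estimate) until a
monotonic clock passes the budget.

**Thresholding** keeps exactly the edges with p ≥ t (inclusive: edges *below*
the threshold are removed) and returns the deterministic modularity of that
single world.  It is accurate only when all probabilities sit near 0 or 1
and the threshold lies strictly between them; the failure-mode comparison
therefore sweeps t over 0.1…0.9.  Including t beyond the largest edge
probability empties any network — including a nearly deterministic one — and
would measure grid misuse rather than the method, so 1.0 is excluded from
that particular comparison (the estimator itself accepts any t ∈ (0, 1]).

**Weighting** evaluates the standard weighted modularity with A_ij = p_ij,
M = total weight and k_i = node strength.  Its closed form depends on the
weights only through ratios, so uniformly scaling all probabilities changes
nothing — the structural reason it cannot estimate E(Q): it confuses "all
edges almost surely absent" with "all edges certain".

## Entropy ratio

Network uncertainty is summarised by (Σ_e h(p_e))/m with h the binary
entropy in **base 2** — the base for which the ratio spans [0, 1], pairing
uniform p = 1.0/0.9/0.5 with ratios 0.00/0.47/1.00.  Its inverse (the
uniform probability achieving a target ratio) is found by bracketed root
finding on [0.5, 1] to 1e−12 ("high" branch; the "low" branch mirrors it).

## Synthetic inputs

Planted-partition (SBM) topologies with parameters (k, nc, p_in, p_out) are
the primary fixtures: the clear-structure CCS network (k=3, nc=9,
p_in=0.99, p_out=0.01 — nearly three 9-cliques) and its less-clear LCCS
counterpart (p_in=0.72, p_out=0.12), both 27 nodes.  ER, BA and
Watts–Strogatz topologies come from networkx with integer seeds; the
forest-fire model is implemented directly (ambassador choice plus geometric
forward burning, default forward probability 0.37) because its role here is
only to induce skewed community sizes, for which approximate fidelity
suffices.  Unequal community sizes for the size-variance study come from a
Dirichlet split of the nodes with a concentration knob.

Edge probabilities are assigned either uniformly or by the entropy-target
scheme: offsets drawn uniformly in a ±0.15 band around a centre on the high
branch, the centre bisected until the realised entropy ratio matches the
target, halving the band when the target is otherwise unreachable
(realisation tolerance ±0.02; assigned probabilities are floored at 1e−3 to
stay in (0, 1]).  The distribution the original experiments drew random
probabilities from is not fixed anywhere, so this scheme is a documented
stand-in; no quantitative conclusion depends on its exact shape.

What the generator does *not* emulate: real confidence-score distributions
(e.g. CDF-transformed interaction weights), correlated edge uncertainty, or
clusterings produced by modularity optimisation on the underlying
deterministic graph (clusterings here are planted or random; external ones
can be supplied as files).  Passing tests therefore demonstrate correctness
of the computation on controlled inputs, not calibration to any particular
real data source.

## Problem sizes and numerical checks

Default test/driver scales: exactness is verified on 100 planted-partition
networks with 9–21 edges (where the 2^m oracle is cheap), engine agreement
up to 500 trials, sampling behaviour with 50 runs of θ = 1000 on the
27-node CCS fixture, and the runtime scaling of FPWP on ER topologies with
m ∈ {100, …, 1000} and 5 random communities, where the log-log slope is
checked against the ≤ 3.5 polynomial bound.  Wall-clock times are always
reported from a monotonic clock and never asserted beyond that slope bound.

## Known limitations

* The joint distribution of Q is exponential-only (see above).
* PWP's enumeration engine is intentionally capped; FPWP is the production
  path.
* Weighted modularity has no resolution parameter and no directed or
  overlapping variants.
* The forest-fire generator controls its edge count only loosely through
  the forward-burning probability.
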