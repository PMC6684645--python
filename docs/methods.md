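# Methods

## Model

A simple undirected graph with n nodes, m edges and density
δ = 2m/(n(n−1)) carries a binary attribute c over its nodes; n₁ nodes are
flagged (c = 1) and n₀ = n − n₁ are not. Each edge is a dyad typed (1-1),
(1-0) or (0-0), with counts m₁₁ + m₁₀ + m₀₀ = m. If the n₁ flags are placed
uniformly at random, every unordered node pair is flagged-flagged with
probability C(n₁,2)/C(n,2), giving the exact expectations
m̄₁₁ = C(n₁,2) δ and m̄₁₀ = n₁ n₀ δ. Dyadicity D = m₁₁/m̄₁₁ and
heterophilicity H = m₁₀/m̄₁₀ measure the observed departure from that null.
Both are undefined when the corresponding expectation vanishes (n₁ ≤ 1 for
D; n₁ ∈ {0, n} for H); the package raises a dedicated error rather than
returning a sentinel.

All expectation and ratio arithmetic is carried in exact rationals
(`fractions.Fraction`) and converted to float only at the interface;
reports round D/H/r to 2 decimals and p-values to 3.

## Extremal bounds and the H–D space

m₁₁ and m₁₀ cannot take arbitrary values: the degree sequence constrains
them. With the degree sequence sorted non-increasing, head(k) denotes its k
largest and tail(k) its k smallest entries (bounds depend only on the
degree multiset, so tie order is irrelevant). The implemented bounds:

- m₁₁ᵘ = min(m, C(n₁,2), ⌈Σ_{head(n₁)} min(dᵢ, n₁−1) / 2⌉)
- m₁₀ᵘ = min(m, n₁n₀, min(Σ_{head(n₁)} min(dᵢ, n₀), Σ_{head(n₀)} min(dᵢ, n₁)))
- m₁₁ˡ = max(0, ⌊(Σ_{tail(n₁)} dᵢ − Σ_{head(n₀)} dᵢ) / 2⌋)
- m₁₀ˡ = 0 if n₁ ∈ {0, n}; otherwise max(1, Σ_{tail(n₁)} dᵢ − n₁(n₁−1)),
  with the floor of 1 replaced by 0 for disconnected graphs — the
  guarantee of at least one cross edge presumes connectivity, so
  connectivity is detected (or passed as a flag) and the relaxation is
  logged. Bounds for m₀₀ follow by the 1 ↔ 0 role swap (n₁ → n₀).

Dividing the bounds by the expectations maps them to
[Hmin, Hmax] × [Dmin, Dmax], a rectangle that always contains the pivot
(1, 1). Its four quadrants are the heterophobic-dyadic (I),
heterophilic-dyadic (II), heterophilic-antidyadic (III) and
heterophobic-antidyadic (IV) regions.

## Relevance

An observed attribute is the point (H, D); its displacement from the pivot
is v = (H−1, D−1) and the diagonal of its region is u, the vector from the
pivot to the region's corner — the longest realizable displacement of that
kind. The relevance is the projection ratio r = (v·u)/(u·u), which is 0 at
the pivot, 1 at the corner, linear along the diagonal, and in [0, 1] for
every point of the rectangle. Because each attribute is normalized within
its own feasible region, attributes with different n₁ (hence different
rectangles) are ranked on a common [0, 1] scale.

Numerical conventions, chosen where the construction is genuinely open:

- Boundary classification is deterministic: H = 1 joins the heterophilic
  side (II/III), D = 1 the dyadic side (I/II); exactly (1,1) is the pivot
  and scores 0.
- Projection is computed in raw (H, D) coordinates with no per-axis
  rescaling, even though Dmax can greatly exceed Hmax; the anisotropy of
  the rectangle is part of the geometry, not noise.
- A collapsed region (zero-length diagonal, e.g. the complete graph where
  bounds equal expectations) scores r = 0.
- A point outside the rectangle is an input-consistency error, not a
  clamped value; inclusion is tested with a 10⁻⁶ tolerance and the final
  ratio clipped to [0, 1] against rounding at the corners.
- Ranking excludes attributes with n₁ ∉ [2, n−2], logging the reason: at
  n₁ ≤ 1 dyadicity is undefined, and at n₁ ≥ n−1 the complementary class
  collapses the usable space. The permutation test accepts the slightly
  wider n₁ ∈ [2, n−1]: with a collapsed space every draw scores r = 0 and
  all p-values are 1, which is well defined.

## Permutation significance

The null reshuffles the metadata vector, not the edges: K draws of a
uniformly random n₁-subset (default K = 1000). Expectations, bounds and
the rectangle depend only on (n, m, n₁, degrees) and are computed once.
p-values are plain proportions with non-strict inequalities (ties qualify,
the conservative choice; no add-one smoothing, so p = 0.000 is reportable).
p_r counts draws with r at least the observed; p_D and p_H are one-sided
in the direction of the observed departure (e.g. for a dyadic-heterophobic
configuration, higher D and lower H qualify; the other regions mirror
this). One permutation set per attribute serves all three p-values. The
seed is a required argument; all randomness flows through
`random.Random(seed)`.

## Phase diagram (exact oracle)

For small graphs, all C(n, n₁) placements are enumerated in lexicographic
node order, accumulating the degeneracy of each realizable (m₁₀, m₁₁)
pair; per subset, m₁₁ is counted over the C(n₁,2) internal pairs and
m₁₀ = Σ degrees − 2m₁₁. The map verifies the closed-form machinery
exactly: every realizable pair lies inside the bounds, the
multiplicity-weighted means equal m̄₁₁ and m̄₁₀ as rationals, and the
multiplicities sum to C(n, n₁). Enumeration is exponential, so a hard cap
(default 2×10⁶ subsets) refuses oversized requests with the exact count
rather than truncating silently.

## Redundancy

Redundancy of two attributes is the cosine between their binary node
vectors in a fixed (sorted-node-id) order: 1 for identical assignments, 0
for disjoint ones; undefined for an all-zero vector. The R-R table pairs
each unordered couple's cosine with both members' relevances; couples
involving an unrankable attribute are omitted rather than padded. Redundant
metadata are reported, never trimmed — the aim is interpretation of which
nodes drive relevance, not feature reduction.

## Input conventions

Edge lists are whitespace-delimited text (override with a flag), `#`
comments, duplicate edges collapsed with a logged count, self-loops
rejected. Metadata are CSV with a header and node ids in the first column.
Numeric attributes are dichotomized at the arithmetic mean, flagging values
strictly greater than it — equality at the mean goes to the 0 bin, a
convention this package fixes since "above average" leaves ties
unspecified; consequently a constant attribute yields n₁ = 0. Mean
thresholding is appropriate for roughly homogeneous distributions; for
fat-tailed attributes a quantile or characteristic-scores split is more
faithful, and is out of scope here.

## Synthetic data

The fixture generators define the conditions everything is tested under:

- `counts_constrained_graph` samples a graph with exact dyad counts
  (m₁₁, m₁₀, m₀₀) by drawing each class's edges uniformly without
  replacement. D and H depend only on the counts, so these fixtures pin
  the metrics regardless of seed. Isolated nodes may occur; connectivity
  is detected downstream for the m₁₀ lower bound.
- `rich_club_toy` is a fixed 43-node, 45-edge connected graph whose four
  flagged nodes form a clique and hold the four highest degrees, with
  (m₁₁, m₁₀, m₀₀) = (6, 37, 2), giving D ≈ 20.07 and H ≈ 4.76. The toy is
  defined by its counts (m₁₀ = 37 because 37/m̄₁₀ rounds to 4.8, while 38
  would round to 4.9); the exact edge placement is this package's own.
- `random_annotated_graph` draws a uniform G(n, m) graph and a uniform
  n₁-subset; the oracle-equivalence and calibration checks run on such
  graphs at n ≤ 12 and n = 25, m = 32 respectively.

What these fixtures do not emulate: degree heterogeneity of real
interactomes beyond the planted hubs, correlated attributes, missing
labels, weighted or directed edges. Passing tests certify the
combinatorics and the statistics of the method, not the fidelity of any
particular biological or economic dataset.

## Problem sizes and tolerances in the test suite

Unit oracles enumerate graphs up to n = 12 (≤ 4096 subsets each, 50 seeded
graphs); the toy's C(43,4) = 123,410 placements enumerate in well under a
second. Calibration uses 200 random annotations at K = 500 on a 25-node
graph, requiring Kolmogorov–Smirnov distance < 0.1 from uniform. The
Monte-Carlo-vs-exact agreement check runs at the three-sigma level; where
the exact fraction is of order 10⁻⁵ the normal ±3·SE band under-covers
(it would reject the legitimate ~0.8%-probability event of redrawing the
observed clique once in K = 1000), so the band is implemented as the exact
binomial tail at α = 0.0027, which coincides with ±3 SE for moderate p.

## Known limitations

- Binary metadata only; dichotomization loses information dependent on the
  threshold.
- The relevance score is a single global index: it compresses where in the
  region a configuration falls and carries no local (per-node) detail, so
  it should be read alongside D, H and the p-values.
- The m₁₀ lower bound of 1 for connected graphs is weak for dense graphs;
  bounds are containment guarantees, not tight envelopes of the realizable
  set (the star example realizes m₁₀ ∈ {2,3} within bounds [1,4]).
- The permutation null fixes the graph and reshuffles labels; it does not
  control for degree sequence under edge rewiring, which answers a
  different question and is deliberately not provided.
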