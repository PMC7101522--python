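# Methods

## Graph model

Every stage operates on an undirected, unweighted simple graph whose nodes
are gene symbols. Self-loops are rejected, reciprocal/duplicate edge rows
collapse to one edge, and degree-0 nodes are first-class (edge-list formats
carry them as single-symbol "node declaration" lines, GraphML natively).
Symbols are whitespace-trimmed but never case-folded: case-folding can merge
distinct gene symbols, while database exports are case-consistent.

STRING-style exports may score edges on a 0–1 or 0–999 scale; a file whose
maximum score exceeds 1 is rescaled by 1/1000. Edges below `min_score`
(default 0.4, the database's "medium confidence" convention) are dropped at
load time, but their endpoint genes stay in the node universe — a gene whose
only interaction was low-confidence is an isolated gene, not an absent one.
Scores are then discarded: all centrality statistics are unweighted, which
matches the GUI network analyzers this pipeline replaces.

## Component census

Connected components are classified as isolated (size 1), small
(2 ≤ size ≤ `small_max`, default 3), or the main component (the largest).
An exact size tie for largest is broken toward the component whose
lexicographically smallest member sorts first, with a logged warning —
determinism matters more than the (arbitrary) choice itself. If the largest
component is itself within the small range it is still the main component;
anything larger than `small_max` that is not the main component is reported
separately (`other`), never silently merged.

## Centrality statistics

For each node *n* of a connected (sub)graph of size *N*:

- **degree** — neighbor count.
- **avg_L** — mean shortest-path length to every other node of its
  component. Averaging over reachable nodes only keeps the value finite;
  callers analyzing a full interactome decompose first and pass the main
  component. For an isolated node the value (and closeness) is undefined
  and recorded as null rather than 0 — the distinction matters downstream.
- **closeness** — `1 / avg_L`, exact at full precision; the relation
  `closeness · avg_L = 1` is an invariant the tests verify, not a rounding
  identity.
- **betweenness** — over unordered pairs `{s, t}` with `s, t ≠ n`:
  `Σ σ_st(n)/σ_st`, normalized by `2/((N−1)(N−2))`, so values lie in
  [0, 1]. The unordered-pair convention is what makes the normalized value
  reach 1.0 for a path's middle node.
- **stress** — the raw number of geodesics through *n* over unordered
  pairs: a pair with three shortest paths through *n* contributes three.
  This is the classical stress definition; it is not a pair count.

Distances and geodesic counts come from one breadth-first search per source
(O(N·E) total); betweenness and stress are assembled per node from the
distance/count matrices with vectorized O(N²) passes, O(N³) overall —
entirely adequate for the few-hundred-node components this pipeline
targets, and simple enough to audit. The test suite checks the
implementation against three independent routes: scipy's Floyd–Warshall
(distances), explicit enumeration of all shortest paths via
`networkx.all_shortest_paths` (betweenness and stress), and
`networkx.betweenness_centrality` (betweenness), plus hand-derived closed
forms for star, path, cycle and complete families.

Reports round avg_L, betweenness and closeness to two decimals;
computation always uses full precision. Note that a two-decimal closeness
printed next to a two-decimal avg_L need not be the rounded reciprocal of
the *printed* avg_L for every row — reciprocal-then-round and
round-then-reciprocal can differ in the last digit.

## Hub selection

A node is a hub when its metric value is **strictly** above
`mean + k·SD` of the metric over the candidate population. Defaults:
metric = closeness, `k = 2`, sample standard deviation (n−1 denominator,
the spreadsheet/statistics convention; a population-SD switch exists for
tools that normalize by n). `k` is a config knob because the field's
reporting oscillates between "mean + 2 SD" and "mean ± SD" for the same
screen; both readings are runnable. An empty selection (homogeneous
component, e.g. a clique) is a warned no-op, not an error: downstream
stages record themselves as "not run".

Selection is scale-equivariant, anti-monotone in `k`, and partitions the
population — all property-tested.

## Sub-network cascade

- **Neighborhood sub-network**: induced subgraph on the seed set plus the
  union of the seeds' direct neighbors.
- **Minimal core**: hub subsets are enumerated exhaustively in order of
  increasing size (2^h subsets; refused above 20 hubs unless the bound is
  raised explicitly). A subset passes the *integrity* criterion when (i)
  its neighborhood sub-network is connected and (ii) every hub — including
  the dropped ones — is still a member of it. Exhaustive enumeration is
  deliberate: it guarantees true minimality, and the test suite re-verifies
  the certificate with an independent re-enumeration. Among minimal-size
  passing subsets the winner maximizes coverage (fraction of the full-hub
  sub-network retained), then ties break lexicographically. If no subset
  passes — possible when the full-hub neighborhood sub-network is itself
  disconnected — the full hub set is returned flagged `integrity_ok =
  False` rather than raising, so a screen on an unusual network still
  produces a complete report.
- **Residual sub-network**: main-component nodes outside the full-hub
  neighborhood sub-network, with degrees taken *within* the residual
  subgraph and the same `mean + k·SD` screen applied to them
  (metric = degree, `k = 2` by default). The residual may be disconnected;
  its components are screened jointly, since the degree metric needs no
  connectivity.

Report accounting distinguishes core seeds, excluded hubs present as
neighbors, and plain neighbors, and carries both the all-members count and
the non-seed count: published figure captions are ambiguous about whether
core genes are included in a sub-network's headline size, and exposing the
three-way split makes either reading checkable by the validator.

## Synthetic generator

`GeneratorConfig` defaults describe a 214-gene interactome: a 159-node main
component, 49 isolated genes, two 3-cliques ("triple units"), 6 planted
hubs, `m_attach = 2`, `hub_boost = 25`. The main component grows
node-by-node, each newcomer wiring `m_attach` edges to uniformly chosen
existing nodes; the hubs are then planted on a uniformly random node
sample, wired into a clique (so the hubs-only sub-network is connected),
and each receives `hub_boost` extra edges to uniformly chosen non-adjacent
non-hub nodes (capped at availability, so a saturating boost produces a
closeness-1.0 dominating hub).

Two design points deserve a note:

- **Uniform (not preferential) attachment by default.** A preferential-
  attachment background conflates positional advantage with the planted
  signal: the earliest nodes dominate closeness whether or not any boost is
  applied, so a "no-signal" control network would still yield near-perfect
  recovery of early-planted hubs, and randomly-planted hubs would compete
  with the natural ones. Uniform attachment keeps a mildly right-skewed
  degree distribution (old nodes are still richer) while leaving the
  boost as the only closeness outlier mechanism, which is precisely what a
  planted-signal recovery experiment needs. Users who want a heavy-tailed,
  scale-free background can set `attachment="preferential"`; recovery
  contrast is weaker there, by construction.
- **Random hub placement.** Hubs are sampled uniformly among main-component
  nodes so that, at `hub_boost = 0`, the planted set is statistically
  indistinguishable from the background — the negative control is a real
  control.

All randomness flows from one `random.Random(seed)` stream; identical
config (including seed) reproduces a byte-identical edge list, and the
generated component census equals the config exactly (property-tested).

`recovery_experiment` runs generate → census → centrality → hub selection
across a seed range and reports per-seed Jaccard overlap between selected
and planted hubs. Under the defaults (50 seeds, `k = 2`) mean recovery is
≈ 0.997; with the boost removed it collapses to ≈ 0.08, and it rises
monotonically over boost ∈ {0, 5, 15, 25}. What the generator does *not*
emulate: confidence-score structure, degree-correlated edge noise,
community structure, or any biological wiring — passing recovery here shows
the statistical machinery is sound under the stated topology, not that a
particular biological screen is correct.

## Pipeline and report

`run_screen` executes census → centrality → hub selection → neighborhood
sub-network → minimal core → residual screen on the main component, with
stage-tagged logging to stderr and results to files: `report.json`,
`centrality.tsv`, `hubs.tsv`, and each sub-network as TSV + GraphML. Every
ordering is fixed (sorted nodes, sorted edges, sorted JSON keys), so
re-running on identical input is byte-identical; the report embeds the
resolved config, the input's SHA-256 node/edge digest, and the node
universe. `validate_report` is a pure function of the report that re-checks
census totals, seed/neighbor accounting, sub-network + residual = main
conservation, the core membership splits, and membership of every named
gene in the input universe (that last rule engages only when the report
carries the universe, so partial count-only reports remain validatable).

## Problem sizes and numerical notes

The test battery uses graphs of ≤ 214 nodes (the default synthetic census)
and oracle graphs of ≤ 20 nodes; exhaustive oracle comparisons run on 200
random connected graphs of 4–12 nodes. Betweenness comparisons use an
absolute tolerance of 1e-12 (the implementation and oracles accumulate the
same rationals in different orders); distances, stress and counts are
compared exactly as integers. Degenerate inputs are defined, not special-
cased: empty networks and empty seed sets raise input errors; single-node
components yield null avg_L/closeness; cliques yield empty hub selections
that short-circuit the cascade with explicit markers.
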