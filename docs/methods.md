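# Methods

## The model of circulation

The object of analysis is an origin–destination flow network built from
sampling-inspection records. Each record is one sampled food item with a
qualification status and two parties: the manufacturer (origin) and the
distributor (destination). After cleaning, only substandard records carry
flow: a directed edge u → v at a given administrative level (province or
city) is weighted by the number of substandard records manufactured in u
and distributed in v. Records whose two parties fall in the same unit
become self-loops. Self-loops carry the *local circulation* mass — the
share of flow that never leaves a unit, reported by `within_unit_fraction`
— but are excluded from every topological statistic (degree, density,
diameter, betweenness, communities, key players), matching the default
behaviour of the network tools practitioners use for these measures. All
reported routes are single-hop because the records name no intermediate
stops; betweenness and reach treat the observed edges as a transmission
substrate under the assumption that quality risk propagates along them.

## Cleaning and geocoding

Cleaning drops records missing either party's address and collapses exact
duplicates on the tuple (status, manufacturer address, distributor address,
food name, sample date), after NFKC width normalization and whitespace
collapsing — Chinese source tables mix full- and half-width characters.
The duplicate key is deliberately conservative (exact match only); no fuzzy
record linkage is attempted. Rows with unparseable status are dropped with
a logged count rather than guessed.

Addresses resolve to (province, city) by keyword lookup in an offline
gazetteer: the longest matching city key wins, then the leftmost
occurrence; any residual tie between distinct units, any pair of distinct
province keywords, and any disagreement between a named province and the
matched city's parent all yield *unresolved* rather than a guess.
Direct-administered municipalities are present as both a province-level and
a city-level unit, so they participate in both networks. Centroids are
carried for display only — no coordinate ever enters a computed statistic,
which is why no datum handling is needed. A single-function plugin contract
(address → lng, lat, province, city) lets a remote geocoder stand in for
the gazetteer on unresolved addresses, with answers cached to CSV so reruns
are reproducible and tests never touch a network.

## Statistics and their conventions

- **Ratio** r_i = weighted in-flow / weighted out-flow by default. The
  unweighted (partner-count) variant sits behind a flag; the volume-based
  reading is the one that matches how net sources and destinations are
  discussed downstream. A node with in-flow but zero out-flow gets +inf
  (pure destination); a fully isolated node gets NaN.
- **Mean degree** is reported in both conventions, e/n and 2e/n, and mean
  weighted degree likewise (mass/n and 2·mass/n), because published
  summary tables are not consistent about which is meant; both are cheap
  and unambiguous when labelled.
- **Diameter** of a directed network that is not strongly connected is the
  longest shortest path over *reachable* ordered pairs of the largest
  weakly-connected component, with the unreachable-pair count reported
  alongside — a single finite number plus an honesty flag.
- **Circulation intensity** = 1000 × (weighted in- or out-flow) /
  (qualified + substandard samples inspected in the unit). Denominators
  come from the full cleaned record set counted at each record's
  distributor unit (where sampling happens); units without a positive
  denominator are flagged unscorable, never silently zeroed.
- **Natural breaks** use the exact Fisher–Jenks dynamic program (O(k·n²)),
  implemented in-package, minimizing total within-class sum of squared
  deviations; class intervals are half-open [lo, hi) with a closed top
  class, and an exhaustive break-placement oracle checks optimality in the
  tests. At the 34-unit scale of a province table the DP cost is trivial.
- **Betweenness** uses Brandes' exact algorithm on the directed graph with
  hop-count distances. Edge weights are flow volumes, not lengths — a tool
  default that treats weight as distance would rank heavy routes as *far*,
  inverting the meaning — so the weighted mode (distance = 1/weight) exists
  but is explicitly non-default. Scores are also reported as percentage
  shares of the total, the presentation used in ranked key-path tables.

## Community detection

Louvain is implemented from its two primitives: exact modularity
Q = 1/(2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j) and the fast gain ΔQ of
absorbing an isolated node into a community, computed from community
aggregates (Σ_in, Σ_tot, k_i, k_i,in with ordered-pair bookkeeping). The
test suite verifies ΔQ ≡ direct Q differences on exhaustive move sets, so
the aggregate formula cannot drift from the definition. Phase 1 sweeps
nodes in a seeded-shuffle order, moving each node to the neighbouring
community with the largest positive gain (ties to the lowest community id);
phase 2 contracts communities to super-nodes, internal weight becoming
self-loops; the pair iterates until Q stops improving. Directed input is
symmetrized (ω(u,v) + ω(v,u)) first, since the quality function is defined
for undirected graphs. The seed is part of the result object; identical
seeds give identical partitions. Resolution defaults to 1. The
highest-betweenness member of each community is reported as its
*gatekeeper* — the node bridging to other communities.

## Key cities

The distance-weighted reach of a set S is D_R = (1/n) Σ_i 1/d(S, i), with
d the minimum hop distance from S, members contributing 1 (self-distance
convention of the original key-player measure) and unreachable nodes 0 —
both conventions stated here because the bare formula leaves them open.
Direction defaults to following edges outward from S (circulation out of
candidate key cities); the undirected mode exists because the original
measure is undirected. Optimization is greedy forward selection plus
best-improvement pairwise swaps under seeded restarts (restart 0 is
deterministic greedy, so the answer never falls below pure greedy);
exhaustive C(n,k) enumeration serves as the oracle at small n and remains
available as `exhaustive_key_players`. The k = 1..k_max profile optimizes
each k independently — membership may churn with k, which is expected.

## Synthetic data: what it emulates, what it does not

Each simulated record draws its destination city proportionally to a
long-tailed base weight (1 + Pareto(weight_tail), hubs multiplied by
hub_attraction), then its source: same city with probability p_within_city,
else same province with probability p_within_province_given_cross_city,
else another province (within the same planted block with probability
p_within_block when blocks are planted). Status is substandard with a fixed
rate; dates are uniform over 2014Q1–2019Q2; addresses are templated from
gazetteer names so geocoding round-trips exactly. Defaults encode the
study conditions of the national analysis this package reproduces: 34
provinces × 11 cities, ≈2,700 samples per city (≈1.0M records), retained
substandard share 2.144%, within-city share 0.572 and within-province share
0.817 (hence p_within_province_given_cross_city = (0.817 − 0.572)/(1 −
0.572) ≈ 0.572).

Two scenario builders create recoverable structure: `plant_two_hub_scenario`
reroutes a fixed share of cross-city substandard flow through two hubs,
each exclusively serving one half of the cities with round-robin partner
coverage so the hub pair is the *unique* two-node set with full distance-1
reach; `block_scenario_config` plants province-blocks with strong
within-block routing and no within-province preference, so blocks are the
only mesoscale structure for Louvain to find.

What the generator does **not** emulate: the strong geographic
concentration of real flows (in reality a handful of provinces source most
cross-province circulation; the generator spreads cross-province flow
nearly uniformly, so the synthetic province network is denser and its
diameter shorter than a real one), spatial adjacency effects (neighbouring
provinces trade more), reporting lags, and address noise (templated
addresses always resolve; resolution-failure handling is exercised by
dedicated fixtures instead). Passing tests therefore demonstrate the
correctness of the pipeline's computations and its recovery power on known
structure — not that real data will show any particular density, community
count, or key-city set.

## Problem sizes and numerical choices

The default test suite runs in seconds: oracle comparisons use exhaustive
enumeration at n ≤ 8 (betweenness), n ≤ 10 (modularity moves and partition
optima), n ≤ 12 with k ≤ 3 (key players), and ≤ 25 values (Jenks); the
parameter-recovery check uses a 50,000-record generator run, where the
realized within-city share must land within three binomial standard errors
of the configured probability. `scripts/acceptance.py` runs the full
pipeline at the default ≈1.0M-record scale in well under a minute on one
CPU. Floating-point ties in gains and reach are broken with a 1e-12
tolerance and deterministic lexicographic order; modularity stored on a
partition is recomputable from the assignment to within 1e-12. Degenerate
inputs (empty networks, zero substandard records, all-self-loop networks,
constant-value classifications, edgeless modularity) raise explicit errors
or warnings rather than returning silent zeros.

## Scope choices

Legacy binary `.xls` input is not read; tables are accepted as `.xlsx` or
CSV (a clear error suggests conversion). Map rendering and interactive
dashboards are out of scope — graph exports (edge-list CSV, GraphML, GEXF)
feed standard visualization tools. Multi-hop route reconstruction is not
attempted because the records contain no intermediate stops.
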