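# circnet

Multilevel circulation-network analysis of food-safety sampling-inspection
records.

Market-surveillance agencies accumulate large tables of sampling-inspection
results: one row per sampled food item, marked *qualified* or *substandard*,
with the free-text addresses of the item's manufacturer and its distributor.
`circnet` turns such tables into directed weighted **circulation networks** —
a node is an administrative unit (province or city), an edge u → v counts the
substandard items manufactured in u and sold in v — and computes the
statistics used to prioritise where regulation effort goes. It is aimed at
food-safety and surveillance analysts who want these analyses reproducible
and tested rather than assembled ad hoc across GUI tools.

## What it computes

For a network with nodes *i*, *j* and edge weights ω<sub>ij</sub>:

- **Degrees and flows** — in/out degree (distinct partners), weighted in/out
  degree (record flows), and the in/out flow ratio r<sub>i</sub> separating
  *net destinations* (r > 1) from *net sources* (r < 1).
- **Density** e/(n(n−1)), directed diameter, component counts, means /
  medians / ranges (both the e/n and 2e/n mean-degree conventions are
  reported).
- **Circulation intensity** — substandard in- or out-flow per 1,000 samples
  inspected in the unit, binned by **Fisher–Jenks natural breaks** into
  Lower/Low/High/Higher classes and combined into four risk-pattern
  quadrants (high-both / net-destination / net-source / low-both).
- **Node and edge betweenness** (exact Brandes on the directed graph,
  hop-count distances), reported raw and as percentage shares — the
  gatekeeper/key-path measure.
- **Louvain community detection**, implemented from the modularity
  Q = 1/(2m) Σ<sub>ij</sub> [A<sub>ij</sub> − k<sub>i</sub>k<sub>j</sub>/2m] δ(c<sub>i</sub>,c<sub>j</sub>)
  with the fast isolated-node gain ΔQ, verified against direct Q differences.
- **Key-city sets** under the distance-weighted reach
  D<sub>R</sub> = (1/n) Σ<sub>i</sub> 1/d(S, i), optimized by greedy
  selection + pairwise swaps with seeded restarts (exact enumeration
  cross-checks it in the tests).

Everything upstream is included: record cleaning (missing-party filtering,
exact-duplicate removal), offline gazetteer geocoding of free-text addresses
to province/city, and a seeded synthetic-data generator with full ground
truth (flow matrix, per-unit totals, planted hubs and community blocks) so
the whole pipeline is testable end to end without any external data.

## Worked example

```bash
circnet simulate --seed 5 --out-dir demo --provinces 3 --cities-per-province 3 --samples-per-city 60
circnet run-all --records demo/records.csv --gazetteer demo/gazetteer.csv --out demo/out --seed 5
```

prints

```
manifest written to demo/out/manifest.json
{"total": 540, "qualified": 525, "substandard": 15}
```

i.e. 540 simulated inspection records were cleaned and geocoded, of which 15
substandard ones form the circulation networks. `demo/out/` then contains
the edge lists, GraphML/GEXF graphs, per-node metric tables and a manifest
in which every number names the operation that produced it. The same
analysis is available in memory:

```python
import circnet as cn
from circnet.pipeline import analyze

records, gazetteer, truth = cn.generate(cn.GeneratorConfig(
    n_provinces=4, cities_per_province=4, samples_per_city=300,
    substandard_rate=0.05, seed=1))
res = analyze(records, gazetteer, seed=1, k_max=3, restarts=3)
city = res["levels"]["city"]
print("records", res["counts"])
print("within city", round(city["within_unit_fraction"]["value"], 3))
print("communities", res["communities"]["n_communities"],
      "Q", round(res["communities"]["modularity"], 3))
print("k=3 reach", round(res["key_players"]["profile"][2]["reach_pct"], 1))
```

```
records {'total': 4800, 'qualified': 4551, 'substandard': 249}
within city 0.518
communities 4 Q 0.237
k=3 reach 87.5
```

Of 4,800 simulated inspections, 249 substandard records form a 16-city
network; 51.8% of substandard flow never leaves its city, Louvain finds the
4 planted province-shaped clusters (modularity 0.237), and 3 well-chosen
cities reach 87.5% of the network under the distance-weighted reach measure.

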