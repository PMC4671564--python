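# reefconnect

Coral reefs are replenished by larvae that drift on ocean currents, so the
fate of any one reef depends on reefs upstream — often in other countries'
waters. `reefconnect` implements a regional connectivity analysis for reef
systems and feeds it into systematic conservation planning: it simulates
coral spawning events as larval transport over a current field, estimates
the source-to-destination connectivity matrix between reef units, summarizes
larval exchange by marine jurisdiction (EEZ), scores reefs by directed-graph
centrality, selects a conservation priority network by simulated annealing
with *asymmetric connectivity boundary costs*, and reports how much of the
selected high-connectivity reef lies outside the existing MPA network.

It is aimed at spatial ecologists and conservation planners who want a
tested, scriptable, fully synthetic-data-capable version of this workflow.

## The model

**Dispersal.** Each reef unit *i* (a cluster of contiguous reef-bearing grid
cells) releases larvae proportional to its reef area. The pelagic density
field q(x, t) evolves by advection–diffusion over the current field (u, v)
(first-order upwind, conservative, CFL sub-stepped), with daily biology:
competent larvae over reef habitat settle at rate *s* = 75 %/day, then
mortality *m* = 20 %/day applies to the remaining pelagic density.
Competency is a gamma CDF truncated to reach 1 at 3 days; the run ends at
the maximum pelagic larval duration (30 days). The event matrix C_ij is the
amount released at *i* that settled on *j* (the diagonal is local
retention); event matrices are averaged and entries with per-released
probability below 10⁻⁶ are discarded as ecologically irrelevant.

**Centrality.** The thresholded matrix defines a directed weighted graph.
Strengths s are mapped to distances x − s (x the smallest whole number
greater than max s), so shortest-path betweenness identifies stepping-stone
reefs and closeness identifies network cores.

**Reserve selection.** A candidate reserve set S is scored with the
Marxan-style objective

    Σ_{i∈S} cost_i + BLM · Σ_{crossing} boundary + Σ_f SPF_f · penalty_f(S) + threshold(t)

where "crossing" boundary entries are directed connectivity values with
exactly one endpoint in S — so the optimizer clumps selections along strong
larval connections. Simulated annealing with iterative improvement is run
over many repetitions (defaults: 30 % targets, SPF 10, BLM 0.17), giving a
best solution and per-unit selection frequencies. A gap table then overlays
the best solution on the MPA layer per marine ecoregion.

## Worked example

```python
import numpy as np
import reefconnect as rc
from reefconnect.summary import local_retention
from reefconnect.centrality import build_network, compute_centralities
from reefconnect.selection import (build_problem, build_connectivity_boundary,
                                   run_scenario, stratify_features)
from reefconnect.gap import compute_gap_table

cfg = rc.SeascapeConfig(rng_seed=42)              # 40x40 grid of 8 km cells
currents, habitat, units = rc.generate_seascape(cfg)
print(f"{len(units)} reef units, {sum(u.total_reef_area_km2 for u in units):.0f} km2 of reef")

params = rc.BioParams()                            # 30 d PLD, 20 %/d mortality, ...
matrices = rc.simulate_events(units, habitat, currents, params)
mean = rc.average_and_threshold(matrices, params)
ret = local_retention(mean)
print(f"mean local retention: {ret.mean():.3f}")

scores = compute_centralities(build_network(mean, units))
print(f"top stepping-stone unit: {scores['betweenness'].idxmax()} "
      f"(betweenness {scores['betweenness'].max():.1f})")

order = [u.unit_id for u in units]
problem = stratify_features(
    build_problem(
        units,
        {"local_retention": ret.reindex(order).fillna(0).to_numpy(),
         "betweenness": scores["betweenness"].reindex(order).fillna(0).to_numpy()},
        boundary=build_connectivity_boundary(mean),
    ),
    units,
)
best, freq = run_scenario(problem, n_reps=25, iterations=50_000, seed=1)
print(f"best solution: {len(best.selected)} units, objective {best.total:.2f}, "
      f"targets met: {all(best.feature_met.values())}")

table = compute_gap_table(units, best.selected).set_index("ecoregion")
print(f"selected reef inside MPAs: {table.loc['TOTAL','pct_selected_in_mpa']:.2f}%")
```

Output:

```
12 reef units, 4776 km2 of reef
mean local retention: 0.150
top stepping-stone unit: 8 (betweenness 43.0)
best solution: 5 units, objective 25.10, targets met: True
selected reef inside MPAs: 50.57%
```

Twelve reef units released larvae over eight simulated spawning events; on
average 15 % of a unit's larvae settle back on their natal reef. Unit 8 is
the strongest stepping-stone in the dispersal network. The connectivity
scenario (30 % targets on local retention and betweenness per ecoregion,
connectivity boundary, BLM 0.17, SPF 10) selects five units meeting every
stratum target; about half of that selected reef area happens to fall inside
the synthetic MPA layer for this seed.

The same pipeline is exposed as a CLI:

```bash
reefconnect generate  --config seascape.yaml --out sea/
reefconnect disperse  --seascape sea/ --events 8 --out conn/
reefconnect summarize --matrix conn/connectivity_dense.csv --released conn/released.csv \
                      --units sea/units.csv --out summ/
reefconnect centrality --matrix conn/connectivity_dense.csv --released conn/released.csv \
                      --units sea/units.csv --out cent/
reefconnect select    --units sea/units.csv --matrix conn/connectivity_dense.csv \
                      --released conn/released.csv --scenario scenario.yaml --out sel/
reefconnect report-gap --units sea/units.csv --solution sel/best_solution.csv --out gap/
```

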