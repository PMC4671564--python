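# Methods

This note documents the models behind `reefconnect`, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic seascape

The generator replaces the external datasets a real regional analysis would
use (archived ocean-model currents, rasterized reef maps, jurisdiction
polygons, a cumulative-threat raster, an MPA database) with self-contained
synthetic equivalents that have the same structure.

* **Currents** are an analytic wind-driven double gyre: streamfunction
  ψ = A sin(πf(x, t)) sin(πy) on the canonical domain x ∈ [0, 2], y ∈ [0, 1],
  with the standard time-dependent boundary f(x, t) (ε = 0.25, one
  modulation cycle over the configured time axis; steady when a single
  timestep is configured). The field is linear in the amplitude parameter
  (peak |u| equals `gyre_amplitude`, in m/s), which makes transport
  behaviour exactly testable; velocities convert internally to cells/hour
  through `cell_size_km`. Fields shorter than a simulation are cycled
  periodically in time.
* **Reef habitat**: `n_reef_clusters` compact blobs grown by seeded random
  accretion within a 2-cell radius of their seed, with per-cell reef areas
  uniform in `reef_area_range_km2` (capped at the cell area). Seeds are
  rejection-sampled with enough pairwise separation that blobs cannot merge,
  so unit count is predictable. Contiguous reef cells are grouped into reef
  units by **8-neighbour (queen) adjacency** — diagonal reef chains are
  ecologically continuous at 8 km resolution. Grid convention: 0-based
  (row, col), row 0 at the north edge, cell centres for centroids.
* **Jurisdictions**: EEZs are longitude (column) bands, ecoregions latitude
  (row) bands of the unit centroid, so the two stratifications cross-cut as
  they do in real basins.
* **Cost**: a smooth sinusoidal surface spanning `cost_range`, averaged over
  each unit's member cells — emulating averaging a 1 km cumulative-threat
  raster over each reef unit.
* **MPA layer**: units are visited in seeded random order and covered in
  full until the regional quota `mpa_fraction x total reef area` is reached;
  only the quota-crossing unit gets partial coverage. This is the simplest
  reproducible quota fill; real MPA boundaries are far more fragmented.

Defaults describe a modest regional domain chosen to be realistic at desk
scale: a 40x40 grid of 8 km cells (the resolution regional reef maps are
commonly gridded at), daily currents over a 30-day cycle, peak speed
0.3 m/s (typical of Caribbean surface currents), twelve reef clusters,
per-cell reef areas 5–64 km², six EEZs, four ecoregions, 25 % of reef area
inside MPAs.

What the generator does **not** emulate: coastline geometry and land
masking (the default domain is open ocean; land masks are supported
end-to-end but not generated), tides and mesoscale eddies, bathymetry, the
skewed size distribution and expert-edited boundaries of real reef maps, or
the spatial clustering of real MPA networks. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions, not
fidelity of any particular regional prediction.

## Dispersal model

Transport is **Eulerian density advection**, not Lagrangian particles:
first-order upwind fluxes in conservative form plus explicit diffusion,
sub-stepped so the combined per-step Courant number is at most 1. This
choice trades numerical diffusion (inherent to first-order upwind) for
exact mass accounting: at every step, released = pelagic + settled + dead +
exited to floating-point precision, which the tests assert at 1e-9
relative. The domain boundary is open (outflow accumulates per source in
`exited`); faces touching land carry no flux.

Biology applies at each 24 h boundary while advection is hourly:

1. **Settlement.** Over reef cells, a fraction `settlement_per_day` x
   competency(age) of the pelagic density moves to the settled tally of the
   unit owning the cell. Competency is a gamma CDF (shape 3 by default,
   scale fixed so the untruncated CDF reaches 0.95 at the full-competency
   age) truncated and rescaled to equal exactly 1 at
   `competency_full_days` = 3 d. The gamma parameters are a modelling
   choice; any parameterization reaching full competency at 3 d is
   admissible, and the truncation makes the endpoint exact.
2. **Mortality.** `mortality_per_day` of the *remaining pelagic* density
   moves to dead, everywhere. Settlement-then-mortality order is a stated
   convention (for unit pelagic density over reef with defaults:
   settled +0.75, pelagic 0.20, dead +0.05 per day). Mortality applies to
   pelagic larvae only, never to already-settled larvae.

Defaults are for broadcast-spawning reef corals: PLD 30 d, mortality
20 %/d, settlement 75 %/d, full competency 3 d, eight spawning events
(event labels default to observed Caribbean mass-spawning dates, used as
metadata only; event start phases are spread evenly over the current
cycle). Released larval units are arbitrary (1 per km² reef by default) —
every downstream quantity is scale-covariant, so connectivity values are
settlement likelihoods rather than larval counts. Horizontal diffusivity
defaults to 1 km²/h (≈ 280 m²/s, within the oceanographic mesoscale range).

Event matrices are averaged entrywise, then entries with per-released
settlement probability below `migration_threshold` = 1e-6 are zeroed. The
threshold applies after averaging and is idempotent.

## Jurisdictional summaries

All summaries consume the same post-threshold averaged matrix used by the
centrality and selection stages. Per EEZ: received and contributed totals,
their external variants (excluding same-EEZ pairs), the within-EEZ block
sum, and the contribution ratio (external contribution over total
contribution). The ratio's denominator **includes** local retention — the
natural reading of "all settled larvae originating in the EEZ"; ratios are
reported to 4 decimals in CSV output, unrounded internally. Per-unit local
retention is the matrix diagonal over the released vector, undefined (NaN)
for units that released nothing.

## Network centrality

Connection strengths s map to distances x − s with x the smallest whole
number strictly greater than max s, preserving reversed rank order.
(Distances are positive; note the sawtooth caveat: raising the *maximum*
strength across an integer boundary raises x and can raise that edge's own
distance — rank order is still preserved.) Betweenness is shortest-path
betweenness on the directed weighted graph with fractional credit among
equal-cost paths, reported **unnormalized** so per-ecoregion sums are
comparable (a normalized variant is an option). Closeness on a directed,
possibly disconnected graph uses **outward** distances over each node's
reachable set with Wasserman–Faust scaling (reachable−1)/(n−1); nodes
reaching nothing score 0. Self-connections (local retention) are not graph
edges, and connections removed by the dispersal threshold are absent rather
than zero-weight. NetworkX provides the graph algorithms; the test suite
checks betweenness exactly against brute-force enumeration of all shortest
paths on small random digraphs.

## Reserve selection

The objective has four terms: summed unit cost; BLM times the boundary
value crossing the selection edge; per-feature shortfall penalties; and an
optional cost-threshold term.

* **Boundary.** Every *directed* entry whose endpoints differ in selection
  status contributes its value once. With asymmetric connectivity values
  this penalizes lost exports and unprotected imports symmetrically in
  status while honouring the asymmetry. Euclidean boundaries are min-max
  scaled centroid distances reversed to [1, 0] (nearest pair → 1);
  connectivity boundaries are off-diagonal strengths max-scaled to [0, 1],
  not reversed. Self-pairs are excluded in both.
* **Penalty.** SPF x (shortfall/target) x a per-feature base penalty equal
  to the cost of a greedy (amount-per-cost) cover meeting the target from
  the empty set. Anchoring the penalty to a realistic cover cost keeps it
  commensurate with the cost term. A consequence worth knowing: with a
  finite SPF the optimum may *narrowly* miss a target when boundary costs
  dominate a small shortfall; raising SPF forces the target.
* **Cost threshold** (disabled by default): a multiplier interpolating
  linearly from `penalty_start` to `penalty_end` over annealing progress,
  applied to the cost excess above the threshold.
* **Annealing.** Single-unit flip proposals from a random initial selection;
  initial temperature is the 90th percentile of |Δ| over 1000 sampled
  flips; geometric cooling to 1e-4 of initial; the best selection seen is
  kept and polished by best-improvement 1-flip local search, so results
  never degrade below the initial selection. Runs are deterministic per
  seed; repetition seeds derive from the scenario seed, and objective ties
  across repetitions go to the earliest repetition. The inner loop is
  numba-compiled; the pure-Python `objective_score` is the reference the
  kernels are tested against (flip deltas are checked to match objective
  differences exactly).

Scenario defaults mirror common regional practice: 30 % targets, SPF 10,
BLM 0.17, 100 repetitions. The per-run iteration default is 100,000 —
scaled down from the million-iteration runs used in full regional analyses,
and configurable up; the bundled tests and the acceptance script use
20,000–50,000 iterations with 5–25 repetitions, which reliably reach the
exhaustively verified optimum on problems of a few dozen units.
Stratification splits each feature into per-ecoregion features (targets =
the target fraction of the stratum total, same SPF); empty strata are
omitted with a warning. Planning problems round-trip through
Marxan-dialect tables (pu / spec / puvspr / bound CSVs plus an `input.dat`
carrying BLM and threshold settings).

## Gap analysis

The gap table sums, per ecoregion and in total, reef area, selected reef
area and selected-area overlap with the MPA layer. A selected unit's
protected area is its stored area-weighted MPA overlap, not a binary
in/out call. Percentages are computed on unrounded sums and formatted to
two decimals; an ecoregion with nothing selected reports 0.00 %. Scenario
comparisons report shared/only counts, areas and the Jaccard index.

## Numerical choices and degenerate inputs

* Mass-balance tolerance 1e-9 relative (tests); conservation is exact up to
  float rounding by construction.
* Upwind advection at Courant number exactly 1 performs exact translation;
  sub-stepping activates only above 1.
* Degenerate boundary scaling (all pairwise distances equal, or only two
  units) yields value 1 with a warning; an all-zero off-diagonal matrix
  yields an empty boundary list with a warning.
* Zero-release units have undefined retention (NaN); zero-contribution EEZs
  have undefined contribution ratio (NaN).
* Annealing with no free units returns the locked configuration; a zero
  sampled temperature is floored at 1e-12.
* Improvement applies flips only when they lower the total by more than
  1e-9, guaranteeing termination.

## Problem sizes

The default test suite runs the dispersal criteria on a 40x40 grid with six
reef units (full 30-day events), the optimizer oracle on one hundred
problems of at most 14 units against exhaustive enumeration, and scenario
behaviour on a seeded 60-unit fixture. The acceptance script uses a 64x64
grid with 24 reef units, eight events, and 25 annealing repetitions of
50,000 iterations per scenario. These sizes were chosen so a complete run
finishes in minutes on one core while every qualitative behaviour of the
full-scale analysis (multi-jurisdiction exchange, stepping-stone structure,
target stratification, boundary-driven clumping) is present.

## Known limitations

* First-order upwind transport is numerically diffusive; fine filaments of
  larval density are smoothed relative to higher-order or particle schemes.
* The double gyre is a caricature of basin circulation; there is no
  mesoscale eddy field, tide, or vertical structure, and larvae have no
  behaviour (no vertical migration, no navigation).
* Biology uses a single parameter set for all reefs; species-specific PLD,
  mortality and competency libraries are out of scope.
* The reserve selector implements the annealing core and objective only —
  no zones, species aggregation rules or separation constraints.
* Synthetic jurisdictions are bands, not realistic polygon geographies, so
  cross-border statistics illustrate structure rather than predict any real
  basin.
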