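# Methods

`waterwalk` simulates daily walking trips between villages and water sources
in a sparsely populated rural landscape, and calibrates the simulated
trip-time distribution against reported travel times. It has four scientific
layers: a land-cover cost surface, a weighted A* router, an agent-based trip
clock, and a binned chi-squared calibration. A synthetic landscape generator
stands in for real GIS inputs.

## The cost surface

The world is a raster of five land-cover classes at 11 m resolution: road,
bare ground, cropland, forest/bush, and river. Each passable class carries a
walking speed and an integer traversal cost:

| class  | speed (km/h) | cost C |
|--------|--------------|--------|
| road   | 6            | 15     |
| bare   | 5            | 38     |
| crop   | 5            | 38     |
| forest | 4            | 90     |
| river  | impassable   | ∞      |

Speeds follow the {4, 5, 6} km/h walking-speed set, with road fastest and
bush slowest. Costs rank classes in the reverse order of speeds, but their
contrast deliberately exceeds the speed contrast: traversal cost models the
*perceived* effort and risk of a surface — dense bush means slow going, poor
visibility and biting flies — not merely its pace. This distinction matters:
if costs were proportional to 1/speed, the route chosen at any
cost-weighting would switch between alternatives exactly where their travel
times are equal, and travel-time data could never identify the weighting.
The absolute cost magnitude, relative to the heuristic scale of 10 per cell,
sets where in the weighting sweep (below) routes transition from direct to
terrain-avoiding; the defaults place that transition inside the swept range.
Both tables are configurable.

The river is impassable everywhere, reflecting rainy-season levels (when
vector exposure is highest). Elevation is not modelled.

## Routing: weighted A*

Routes are computed on the 8-connected grid with scores

    f(n) = g(n) + h(n),        h(n) = 10 · (Euclidean cell distance to goal)

and a per-step move increment `C(class entered) · α · s`, where `s` = 1 for
cardinal and √2 for diagonal steps. α ≥ 0 weights terrain cost against
directness: α = 0 is a greedy straight-line control, large α approaches the
least-cost route. Ties on f break on lower h, then row-major order; cells
are never re-expanded.

Two accumulation modes exist:

* `standard`: g(child) = g(parent) + increment. Textbook A*. With the
  default tables the heuristic is admissible for every α ≥ 1, so the search
  is exact: its terrain cost equals Dijkstra's (this is verified against a
  hand-rolled Dijkstra with identical tie-breaking, against
  `scipy.sparse.csgraph`, and against exhaustive path enumeration on tiny
  grids). The price of exactness is that the whole α-sweep collapses onto
  one least-cost family.
* `as_printed`: g(child) = f(parent) + increment, i.e. the parent's
  heuristic folds into the accumulated cost at every step. The minimised
  objective is Σ(h(parent) + α·C·s) along the path, so the route family
  deforms continuously with α from direct (α = 0) to least-cost (α → ∞).
  This mode is the default for the calibration sweep, where α must be a
  meaningful axis; `standard` remains the default for plain routing.

A separate `dijkstra_path` provides the exact least-cost oracle, and
`path_metrics` computes the deterministic walking time
Σ step_length / speed(entered cell) — the expectation against which the
stochastic clock is unbiased.

## The agent clock

Time advances in 18 s iterations (4800 per day — fine enough to resolve
trips under 5 minutes). Within an iteration an agent takes whole steps while
the remaining budget allows; a step of duration t that only partly fits
(remaining budget r < t) is taken with probability r/t, making the expected
distance per iteration exactly the deterministic budget. The final, partly
used iteration is counted with probability (time used)/18 s. With both
rules, the recorded trip time — always a whole number of iterations — is an
unbiased estimator of the deterministic walking time (verified to ±0.01 min
over 20 000 walks of a 15-minute path). Single-trip deviations behave like a
random walk: bounded by two iterations plus one step on short trips, growing
as √(iterations) on long ones.

Each agent lives in a village (assigned uniformly at random), and fetches
water from the nearest borehole within the borehole threshold (straight-line
distance), otherwise from one of the three
closest riverine sites, chosen uniformly once per agent. Riverine sites are
a seeded sample of 1000 river-bank cells; candidates across the impassable
river from a village are excluded by connected-component analysis. Return
trips under load are not modelled.

## Calibration

Simulated trip-time distributions are compared with observed (reported)
times by Σ (O−E)²/E over k = 5 bins: O are simulated counts, E the observed
bin proportions scaled to the simulated sample size, df = k−1 = 4, 95%
critical value 9.488. Bin edges sit at quintiles of the observed sample,
with inner edges snapped to midpoints between adjacent distinct values so
that no support point of the discrete trip-time distribution lies exactly on
a boundary; bins with expected counts under 5 merge from the top (long-trip
tail) down. The sweep evaluates the 6 × 6 grid of α ∈ {0,5,15,25,35,45} ×
threshold ∈ {0.5,1,2,3,4,5} km, with repeats under common random numbers
(every cell re-uses the same per-repeat seeds), reporting mean ± sd per cell
and flagging the minimum-mean and non-significant cells.

A single-agent-per-village rerun in deterministic-expectation mode (trip
time = ideal time, no clock randomness) gives reproducible per-village
signed errors; √|error| is exported for spatial plotting.

## The synthetic landscape

The generator emulates a river-valley transect: a sinuous west–east river
(impassable, 8-connected, spanning the grid), a riparian bush belt of
varying width (15–40 cells) pierced by a few clear corridors down to the
water, a road tracking the smoothed river trend on the settled bank, a
patchy forest/crop/bare mosaic (thresholded smoothed Gaussian noise; class
fractions accurate to a few percent), villages placed in a 0.3–2.2 km band
from the river, and boreholes placed so their nearest-village distances
spread across 0.55–2.5 km. The village band makes one-way walk times span
roughly 4–45 minutes, the range typical of rural water-collection surveys;
the borehole banding guarantees that successive threshold values actually
flip some villages between borehole and riverine sources, which is what
makes the threshold axis identifiable.

What the generator does **not** emulate: real land-cover spatial statistics
(it is smoothed noise, not a classified image), desire paths, fords,
seasonal river variation, household-level settlement structure, or
elevation. Calibration results on synthetic landscapes therefore validate
the machinery — route computation, the clock, the statistic, parameter
recovery — not any claim about a particular real landscape.

## Identifiability: what recovery experiments show

Planting known parameters (α* = 25, threshold* = 1 km), simulating an
observed sample, and sweeping recovers the **threshold** essentially always:
each threshold step moves whole villages between sources, shifting minutes
of travel time. The **cost weighting** is recovered only coarsely: the
extremes (α = 0, 5 vs 25, and usually 45) separate, but neighbouring values
around the optimum often tie. This is structural, not a sample-size issue:
somewhere along the α-family the route passes through its time-optimal
valley, where adjacent-α time differences are second order, and at walking
speed contrasts of 4–6 km/h a different route rarely changes travel time by
more than a few percent. Travel-time data alone therefore identify the
directness-vs-cost trade-off only up to a neighbourhood. On the standard
landscape, 20-trial recovery of the exact planted cell runs around 65%
(all misses are α-neighbour confusions at the recovered threshold).

## Numerical and protocol choices

* Diagonal moves: exact √2 step factors for cost and geometry (integer
  10/14-style rounding available via `diagonal_step_factor`).
* Determinism: every stochastic component takes an explicit seed; a master
  seed derives per-module seeds by hashing. Identical seeds give
  byte-identical outputs.
* Recovery protocol sizes (chosen once): observed sample 1500 reports,
  sweep runs 2000 agents, 10 repeats per cell, 20 trials; libraries of A*
  routes are precomputed per α and shared.
* Degenerate inputs: empty observed samples, all-one-bin distributions,
  unreachable goals, villages on river cells and malformed rasters all raise
  typed errors naming the offending value or line.

## Known limitations

* α is weakly identified near the optimum (above); report a neighbourhood,
  not a point estimate, when calibrating real data.
* The as-printed accumulation mode is a search heuristic, not an optimal
  planner; its routes have no optimality guarantee (by design — it is the
  behavioural model).
* One trip per agent per simulation; collection frequency, chained
  activities and loaded return walks are out of scope.
* The borehole threshold is evaluated on straight-line distance; a
  path-distance variant would need routes to every borehole and is not
  implemented.
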