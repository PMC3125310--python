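# Methods

## Travel-time model

A road network is a planar graph: intersections (each carrying one of
three controls — none, stop sign, traffic light) joined by road
segments with a polyline geometry, a posted speed limit in km/h and a
road class. All geometry lives in a projected planar CRS with metre
units; geographic input must be projected before loading, since every
length in the model is a Euclidean arc length.

Traversing a segment costs its kinematic time,

    t = L / (v · f),    v = speed limit in m/s,  f = vehicle speed factor,

plus a fixed impedance for the intersection being *entered* at the far
end: 0 s (uncontrolled), 5 s (stop sign) or 10 s (traffic light). Two
boundary rules remove double counting: no impedance is charged at the
trip's origin point, and none at the final destination — an ambulance
arriving at the hospital does not wait at the last light. Segments are
traversable in both directions unless flagged one-way.

Back roads and logging roads are removed before any computation; the
excluded class set is configurable.

### Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `max_segment_length_m` | 200 | m | discretization cap; controls origin-resolution vs table size |
| `stop_sign_delay_s` | 5 | s | impedance entering a stop-controlled intersection |
| `traffic_light_delay_s` | 10 | s | impedance entering a signalised intersection |
| `vehicle_speed_factor` | 1.0 | – | multiplier on posted limits; >1 models an ambulance exceeding them |
| `excluded_road_classes` | {back_road, logging_road} | – | classes dropped before discretization |

The ambulance-vs-car speed difference has no established magnitude, so
the factor defaults to the neutral 1.0 and is exposed rather than
guessed.

## Discretization

A segment at or below the cap passes through unchanged (equality keeps
the segment whole, so the invariant reads `length ≤ max`). A longer
segment is cut into k = ⌈L/max⌉ parts of equal arc length. Equal parts
— rather than fixed 200 m steps with a short remainder — minimise the
worst-case distance from any point on the part to its centroid and are
trivially reproducible. Part ids are `parentid:index`, so rebuilt
tables are stable across runs, and split points become impedance-free
graph nodes chaining the parts together. Child lengths sum to the
parent within 1e-6 relative tolerance (shapely's `substring` is exact
up to floating-point rounding).

Each part is represented by its **centroid**: the point at half the
part's arc length, on the line itself, not the chord midpoint. The
centroid is the travel-time origin for everything snapped to that part.

## The origin–destination table

For every (part centroid, hospital) pair the table stores the minimum,
over all paths, of the summed traversal times:

* the trip starts at the centroid and first covers the residual of the
  origin part toward either end (respecting one-way direction);
* it ends at the hospital's snapped point on its part, paying only the
  partial kinematic traversal (no destination impedance);
* when origin and hospital share a part, the direct on-part traversal
  competes with paths that leave and return.

The implementation runs one Dijkstra per hospital over the reversed
traversal graph and assembles per-centroid times analytically from the
origin residuals — hospitals are few, centroids many, so H searches
beat N×H point queries. The contract is algorithm-independent; the test
suite checks the table against an exhaustive simple-path enumeration
oracle (with branch-and-bound pruning) on random small networks and
against the Manhattan closed form on uniform grids, and the forward
single-pair search mirrors the reversed batch search as a third route.

Times are stored in **seconds** and rounded to whole minutes (round
half up) only at the reporting boundary; storing minutes would destroy
information the validation statistics need. Unreachable pairs carry an
explicit flag, never a sentinel number. The table persists as a CSV
plus a JSON metadata sidecar holding the config snapshot and a SHA-256
fingerprint of the network; loading a table against a different network
fails unless forced.

Snapping (incident locations and hospital ER entrances alike) picks the
part with minimal Euclidean distance to the point, ties to the lowest
part id; an STRtree accelerates the nearest-part query and is built
lazily once per layer.

## Hospitals, queries, allocation

Hospitals carry the Canadian trauma-level designation 1–4, with 9
marking a non-trauma hospital; capacity is the number of critically
injured patients the hospital can accept in the current incident, and
both capacity and inclusion are session-editable. Treatment
specializations travel as a free-text tag column that is displayed but
never used by the ranking.

A query snaps the incident, looks up every included hospital and
returns rows sorted by driving time (unreachable last, ties by id).
Allocation formalises the qualitative preference for close major trauma
centres with a non-trauma fallback as a greedy policy: patients are
assigned one at a time to the nearest hospital with residual capacity
in the highest non-empty tier, with tiers {1,2} ≻ {3,4} ≻ {9}. Only a
full hospital (capacity 0) diverts patients — "busy" states have no
data to model. The tier structure is a parameter so other policies can
be compared. The policy is deterministic, conserves patients
(assigned + unassigned = n), never exceeds a starting capacity, and
adding capacity can only reduce the unassigned count.

## Validation

Deviations are defined as model − ambulance in minutes (positive =
model overestimates). Trip filtering keeps departures inside clock
windows that are closed at the start and open at the end —
[19:00, 07:00) wrapping midnight, and [12:00, 15:00) — the off-peak
periods in which posted limits best approximate achievable speeds.
Records lacking a departure time survive only an empty window list.
Same-origin/destination groups report trip count, whether the model
time is the single constant it should be, and the ambulance min/max/
spread. The paired model/ambulance times are emitted as CSV for
external plotting rather than as a rendered figure.

The bundled transfer log (11 trips between a suburban hospital, SMH,
and a regional trauma centre, RCH) has a constant 13-minute model time
against ambulance times of 8–27 minutes; its mean deviation is
10/11 ≈ 0.91 min.

## Synthetic cities

The generator emits grid cities: intersections every `spacing_m`
metres, independent per-intersection controls (stop with `p_stop`,
light with `p_light`), per-edge speeds drawn from a candidate set, a
fraction of edges bulged into polylines of length `spacing·√2` (to
exercise discretization), and hospitals placed a quarter-block along an
edge incident to a randomly chosen intersection, mimicking ER-entrance
geocoding. One integer seed drives a single `numpy` generator stream,
so outputs are byte-identical across runs.

A grid was chosen over random planar topology because uniform-speed,
zero-control grids admit an exact closed form — block time × Manhattan
steps plus origin/destination residuals — which serves as an
independent oracle at scale.

What the grid does *not* emulate: irregular street morphology, turn
restrictions, one-way systems, congestion, and spatially correlated
control placement. Passing tests therefore demonstrate correctness of
the computation on networks satisfying the model's assumptions, not
calibration against real traffic.

The synthetic ambulance log draws random reachable (part, hospital)
pairs with a model time of at least one minute (a real log has no
zero-minute rows), and sets the observed time to the rounded model time
plus integer-rounded Gaussian noise, floored at 1 min, with an optional
outlier fraction receiving k-fold noise — the long-tail structure real
logs show. Because of the 1-minute floor, the zero-mean property of the
noise only carries over to the deviations when trips are long relative
to the noise; the noise-recovery checks therefore run on a validation
city whose trip durations match the scale of real inter-hospital
transfers (20×20 grid, 400 m blocks, 30/50 km/h, two hospitals; model
times up to ~17 min, comparable to the 8–27 min logged range). On the
small default city (1–4 min trips) the floor binds often enough to bias
the mean, which is a property of minute-rounded short trips, not of the
estimator.

## Problem sizes and numerical choices

* Oracle agreement runs on networks of ≤ 8 intersections (before
  discretization), where exhaustive enumeration is feasible; agreement
  is asserted to 1e-9 relative tolerance, the tightest band meaningful
  across different floating-point summation orders.
* The closed-form check uses a 20×20 grid (760 segments, 5 hospitals).
* The latency check uses a ~10⁴-part city (60×60 grid, half the edges
  over-length); a post-precompute query answers in well under a second.
* Equality-adjacent comparisons on lengths use relative tolerance 1e-6,
  matching the discretization conservation contract.
* Minute rounding is round-half-up everywhere (750 s → 13 min), chosen
  once so model and log minutes are comparable.

## Known limitations

* No turn restrictions, lane modelling, time-of-day speeds or real-time
  traffic; a pre-computed table cannot reflect incident-day closures.
* Patients are homogeneous; injury-type matching to hospital services
  is out of scope.
* "Busy" (as opposed to full) hospitals are not modelled.
* Real-time hospital-capacity feeds are not integrated; capacities are
  session-local edits.
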