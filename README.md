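# mcitriage

Spatial decision support for mass-casualty-incident (MCI) evacuation.

During an MCI, the on-scene decision of *which hospital gets which
patient* has to weigh driving time, trauma-centre capability and bed
capacity — in seconds, not minutes. `mcitriage` makes that possible by
moving all of the expensive work ahead of the incident: it discretizes a
road network into segments of at most 200 m, precomputes the shortest
driving time from every segment centroid to every hospital, and answers
incident-time queries with constant-time table lookups.

The package provides, as a library plus a thin CLI:

* **Road network model** — planar graph of intersections and segments
  with posted speed limits; fixed impedances for stop signs (5 s) and
  traffic lights (10 s), charged on entering a controlled intersection
  and never at the trip's destination; back roads and logging roads
  excluded; an adjustable vehicle speed factor for ambulances.
* **Discretization** — segments longer than 200 m are split into
  ⌈L/200⌉ equal-arc-length parts; each part's centroid (the point at
  half its arc length) is the travel-time origin for that part.
* **OD driving-time table** — for each hospital, a single shortest-path
  search over the reversed traversal graph yields the time from every
  centroid; times are stored in seconds and rounded (half up) to
  minutes only on output.
* **Hospital registry** — ER-entrance locations, Canadian trauma-level
  designation 1–4 (with 9 marking non-trauma hospitals), and editable
  per-incident capacities.
* **Triage queries and allocation** — ranked hospital tables for an
  incident location, and a greedy capacity-aware patient allocation
  within priority tiers: trauma levels {1,2} first, then {3,4}, then
  non-trauma {9}.
* **Validation** — model-vs-ambulance deviation summaries at minute
  granularity, with off-peak time-window filtering (19:00–07:00 and
  12:00–15:00) and same-origin/destination variability statistics. A
  small logged transfer dataset (11 trips, SMH→RCH) ships with the
  package.
* **Synthetic cities** — seeded grid-city generator (controls, mixed
  speeds, over-length segments, hospitals) so everything is testable
  without proprietary road data.

## Worked example

```python
from mcitriage import (ModelConfig, CitySpec, generate_city, discretize_network,
                       snap_hospitals, precompute_od, query_mci,
                       allocate_patients, report)

cfg = ModelConfig()                      # 200 m cap, 5 s stop, 10 s light
net, hospitals = generate_city(CitySpec(seed=7))
layer = discretize_network(net, cfg)     # 180 segments -> 199 parts
snap_hospitals(hospitals, layer)
table = precompute_od(net, layer, hospitals, cfg)   # 995 entries

result = query_mci((410, 390), "rail station", hospitals, table, layer)
print(report(result))
plan = allocate_patients(result, 10, hospitals)
print(report(plan))
```

```
hospital_id  name        trauma_level  capacity  driving_time_min  reachable
-----------  ----------  ------------  --------  ----------------  ---------
h2           Hospital 2  9             13        2                 True
h1           Hospital 1  4             12        2                 True
h3           Hospital 3  2             13        2                 True
h0           Hospital 0  2             6         2                 True
h4           Hospital 4  1             6         3                 True
```

The ranked table lists every included hospital by driving time from the
snapped incident location. Although the non-trauma hospital `h2` is
nearest, the allocation sends all ten critical patients to `h3`: it is
the closest hospital in the highest-priority tier (trauma level 2) with
capacity for all of them. Had `h3` been full, the overflow would spill
to the next tier and finally to `h2`.

The same pipeline is scriptable:

```sh
mcitriage synth --rows 10 --cols 10 --seed 7 \
    --out-network city.geojson --out-hospitals hospitals.csv
mcitriage precompute --network city.geojson --hospitals hospitals.csv --out table.csv
mcitriage query --network city.geojson --hospitals hospitals.csv \
    --table table.csv --x 410 --y 390 --ref "rail station"
mcitriage validate --trips trips.csv
```

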