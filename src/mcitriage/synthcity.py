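"""Seeded synthetic grid cities.

Every other module is testable without proprietary regional road data:
this generator emits a planar grid city — intersections with randomly
placed stop signs and traffic lights, edges with mixed posted speeds, a
configurable fraction of long bulged segments (exceeding the
discretization maximum, to exercise splitting), and a handful of
hospitals of varying trauma level offset onto segments adjacent to their
intersection, mimicking ER-entrance geocoding.

A grid (rather than a random planar graph) is deliberate: with uniform
speeds and no controls, shortest driving times have a Manhattan closed
form, giving an exact oracle for the precomputed table.  All randomness
flows from the single integer seed in the spec.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import time as clock_time
from pathlib import Path

import numpy as np

from .hospitals import Hospital, HospitalRegistry
from .network import (
    CONTROL_LIGHT,
    CONTROL_NONE,
    CONTROL_STOP,
    Intersection,
    RoadNetwork,
    make_segment,
)
from .odmatrix import DrivingTimeTable, round_minutes
from .validation import TripRecord

DEFAULT_TRAUMA_MIX = {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 9: 0.2}


@dataclass(frozen=True)
class CitySpec:
    rows: int = 10
    cols: int = 10
    spacing_m: float = 200.0
    speed_set_kmh: tuple = (30.0, 50.0, 60.0)
    p_stop: float = 0.2
    p_light: float = 0.1
    long_segment_fraction: float = 0.1
    n_hospitals: int = 5
    trauma_level_mix: dict = field(default_factory=lambda: dict(DEFAULT_TRAUMA_MIX))
    capacity_range: tuple = (2, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid dimensions must be >= 2")
        for p in (self.p_stop, self.p_light, self.long_segment_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_stop + self.p_light > 1.0:
            raise ValueError("p_stop + p_light must be <= 1")
        if self.n_hospitals > self.rows * self.cols:
            raise ValueError("more hospitals than intersections")
        if not self.speed_set_kmh:
            raise ValueError("speed_set_kmh must be non-empty")


def node_id(r: int, c: int) -> str:
    return f"n{r}_{c}"


def parse_node_id(nid: str) -> tuple:
    r, c = nid[1:].split("_")
    return int(r), int(c)


def generate_city(spec: CitySpec):
    """Build a grid city; returns ``(RoadNetwork, HospitalRegistry)``.

    Deterministic for a given spec (including seed): two identical specs
    yield identical networks, controls, speeds and hospitals.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing_m

    intersections = {}
    for r in range(spec.rows):
        for c in range(spec.cols):
            u = rng.random()
            if u < spec.p_stop:
                control = CONTROL_STOP
            elif u < spec.p_stop + spec.p_light:
                control = CONTROL_LIGHT
            else:
                control = CONTROL_NONE
            intersections[node_id(r, c)] = Intersection(
                node_id=node_id(r, c), x=c * s, y=r * s, control=control
            )

    edges = []  # (segment_id, from(r,c), to(r,c), horizontal?)
    for r in range(spec.rows):
        for c in range(spec.cols):
            if c + 1 < spec.cols:
                edges.append((f"e{r}_{c}h", (r, c), (r, c + 1), True))
            if r + 1 < spec.rows:
                edges.append((f"e{r}_{c}v", (r, c), (r + 1, c), False))

    segments = {}
    for sid, (r0, c0), (r1, c1), horizontal in edges:
        p0 = (c0 * s, r0 * s)
        p1 = (c1 * s, r1 * s)
        speed = float(rng.choice(spec.speed_set_kmh))
        if rng.random() < spec.long_segment_fraction:
            # bulge the midpoint perpendicular to the edge: arc length
            # 2*sqrt((s/2)^2 + (s/2)^2) = s*sqrt(2), always over a maximum
            # of s (so discretization has work to do)
            off = s / 2.0 * (1 if rng.random() < 0.5 else -1)
            mid = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0)
            bulge = (mid[0], mid[1] + off) if horizontal else (mid[0] + off, mid[1])
            polyline = [p0, bulge, p1]
        else:
            polyline = [p0, p1]
        segments[sid] = make_segment(
            segment_id=sid,
            from_node=node_id(r0, c0),
            to_node=node_id(r1, c1),
            polyline=polyline,
            speed_limit_kmh=speed,
            road_class="road",
        )

    network = RoadNetwork(intersections=intersections, segments=segments,
                          crs_note="synthetic grid city, planar metres")

    # hospitals at distinct intersections, offset a quarter-block along one
    # incident edge (stand-in for the ER entrance on an adjacent street)
    all_nodes = sorted(intersections)
    chosen = rng.choice(len(all_nodes), size=spec.n_hospitals, replace=False)
    levels = list(spec.trauma_level_mix)
    probs = np.array([spec.trauma_level_mix[l] for l in levels], dtype=float)
    probs /= probs.sum()
    registry = HospitalRegistry()
    for i, idx in enumerate(sorted(chosen)):
        nid = all_nodes[idx]
        incident = sorted(
            (seg for seg in segments.values() if nid in (seg.from_node, seg.to_node)),
            key=lambda g: g.segment_id,
        )
        seg = incident[int(rng.integers(len(incident)))]
        line = seg.geometry
        frac = 0.25 if seg.from_node == nid else 0.75
        pt = line.interpolate(frac, normalized=True)
        level = int(levels[int(rng.choice(len(levels), p=probs))])
        lo, hi = spec.capacity_range
        registry.add(
            Hospital(
                hospital_id=f"h{i}",
                name=f"Hospital {i}",
                x=pt.x,
                y=pt.y,
                trauma_level=level,
                capacity=int(rng.integers(lo, hi + 1)),
            )
        )
    return network, registry


def manhattan_grid_time(spec: CitySpec, steps: int, speed_kmh: float) -> float:
    """Closed-form seconds for ``steps`` grid blocks at a uniform speed."""
    return steps * spec.spacing_m / (speed_kmh / 3.6)


def generate_trip_log(
    table: DrivingTimeTable,
    n_trips: int,
    noise_sd_min: float,
    seed: int,
    outlier_fraction: float = 0.0,
    outlier_k: float = 5.0,
) -> list:
    """Synthetic ambulance log drawn from a driving-time table.

    Each trip picks a random reachable (part, hospital) pair; the logged
    ambulance time is the rounded model time plus integer-rounded Gaussian
    noise (floored at 1 min), with an ``outlier_fraction`` of trips
    receiving ``outlier_k`` times the noise — the long-tail structure real
    logs show.  Departure times are uniform over the day.
    """
    rng = np.random.default_rng(seed)
    # only trips of at least a minute: an ambulance log has no zero-minute rows
    reachable = sorted(
        k for k, v in table.entries.items() if v is not None and round_minutes(v) >= 1
    )
    if not reachable:
        raise ValueError("table has no reachable pairs of at least one minute")
    records = []
    for _ in range(n_trips):
        dseg_id, hospital_id = reachable[int(rng.integers(len(reachable)))]
        model_min = round_minutes(table.entries[(dseg_id, hospital_id)])
        sd = noise_sd_min * (outlier_k if rng.random() < outlier_fraction else 1.0)
        noise = int(np.round(rng.normal(0.0, sd))) if sd > 0 else 0
        minute_of_day = int(rng.integers(24 * 60))
        records.append(
            TripRecord(
                origin=dseg_id,
                destination=hospital_id,
                depart_time=clock_time(minute_of_day // 60, minute_of_day % 60),
                model_min=model_min,
                ambulance_min=max(1, model_min + noise),
            )
        )
    return records


def write_trip_log(records, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["origin", "destination", "depart_time", "model_min", "ambulance_min"])
        for r in records:
            depart = "" if r.depart_time is None else r.depart_time.strftime("%H:%M")
            writer.writerow([r.origin, r.destination, depart, r.model_min, r.ambulance_min])
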