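"""Road-network representation and per-segment travel times.

The network is a planar graph: intersections (optionally controlled by a
stop sign or traffic light) joined by road segments carrying a posted
speed limit and a road class.  Travel time over a segment is the kinematic
time at the posted limit (scaled by the vehicle speed factor) plus the
impedance of the intersection being *entered* at the far end.  The
impedance is never charged at a trip's final destination — a vehicle
arriving at the hospital does not wait at the last light.

Geometry is strictly planar: coordinates are projected metres and all
lengths are Euclidean arc lengths.  Geographic (lon/lat) data must be
projected before loading.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from shapely.geometry import LineString

from .config import ModelConfig

CONTROL_NONE = "none"
CONTROL_STOP = "stop_sign"
CONTROL_LIGHT = "traffic_light"
CONTROLS = (CONTROL_NONE, CONTROL_STOP, CONTROL_LIGHT)

# file-level spellings accepted for intersection controls
_CONTROL_ALIASES = {
    "none": CONTROL_NONE,
    "stop": CONTROL_STOP,
    "stop_sign": CONTROL_STOP,
    "light": CONTROL_LIGHT,
    "traffic_light": CONTROL_LIGHT,
}
_CONTROL_FILE_NAMES = {CONTROL_NONE: "none", CONTROL_STOP: "stop", CONTROL_LIGHT: "light"}

_ENDPOINT_TOL = 1e-6  # metres; segment endpoints must coincide with node coords


@dataclass(frozen=True)
class Intersection:
    node_id: str
    x: float
    y: float
    control: str = CONTROL_NONE

    def __post_init__(self) -> None:
        if self.control not in CONTROLS:
            raise ValueError(f"intersection {self.node_id}: unknown control {self.control!r}")


@dataclass(frozen=True)
class RoadSegment:
    segment_id: str
    from_node: str
    to_node: str
    polyline: tuple  # ((x, y), ...)
    length_m: float
    speed_limit_kmh: float
    road_class: str = "road"
    one_way: bool = False

    def __post_init__(self) -> None:
        if self.speed_limit_kmh <= 0:
            raise ValueError(f"segment {self.segment_id}: speed limit must be positive")
        if len(self.polyline) < 2:
            raise ValueError(f"segment {self.segment_id}: polyline needs >= 2 points")
        arc = LineString(self.polyline).length
        if arc <= 0:
            raise ValueError(f"segment {self.segment_id}: zero-length polyline")
        if not math.isclose(arc, self.length_m, rel_tol=1e-6):
            raise ValueError(
                f"segment {self.segment_id}: declared length {self.length_m} "
                f"!= polyline arc length {arc}"
            )

    @property
    def geometry(self) -> LineString:
        return LineString(self.polyline)


def make_segment(
    segment_id: str,
    from_node: str,
    to_node: str,
    polyline,
    speed_limit_kmh: float,
    road_class: str = "road",
    one_way: bool = False,
) -> RoadSegment:
    """Construct a segment with its length derived from the polyline."""
    coords = tuple((float(x), float(y)) for x, y in polyline)
    return RoadSegment(
        segment_id=segment_id,
        from_node=from_node,
        to_node=to_node,
        polyline=coords,
        length_m=LineString(coords).length,
        speed_limit_kmh=speed_limit_kmh,
        road_class=road_class,
        one_way=one_way,
    )


@dataclass
class RoadNetwork:
    """Validated container for intersections and segments."""

    intersections: dict = field(default_factory=dict)  # node_id -> Intersection
    segments: dict = field(default_factory=dict)  # segment_id -> RoadSegment
    crs_note: str = "projected planar CRS, metres"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for seg in self.segments.values():
            for end, node_id in (("from_node", seg.from_node), ("to_node", seg.to_node)):
                if node_id not in self.intersections:
                    raise ValueError(
                        f"segment {seg.segment_id}: dangling {end} reference {node_id!r}"
                    )
            a = self.intersections[seg.from_node]
            b = self.intersections[seg.to_node]
            p0, p1 = seg.polyline[0], seg.polyline[-1]
            if math.dist(p0, (a.x, a.y)) > _ENDPOINT_TOL or math.dist(p1, (b.x, b.y)) > _ENDPOINT_TOL:
                raise ValueError(
                    f"segment {seg.segment_id}: polyline endpoints do not coincide "
                    f"with nodes {seg.from_node}/{seg.to_node}"
                )

    def control_at(self, node_id: str) -> str:
        return self.intersections[node_id].control

    def with_control(self, node_id: str, control: str) -> "RoadNetwork":
        """Copy of the network with one intersection's control replaced."""
        if node_id not in self.intersections:
            raise KeyError(node_id)
        nodes = dict(self.intersections)
        nodes[node_id] = replace(nodes[node_id], control=control)
        return RoadNetwork(intersections=nodes, segments=dict(self.segments), crs_note=self.crs_note)

    def fingerprint(self) -> str:
        """Stable digest of the network topology, geometry and attributes."""
        h = hashlib.sha256()
        for nid in sorted(self.intersections):
            n = self.intersections[nid]
            h.update(f"N|{nid}|{n.x:.6f}|{n.y:.6f}|{n.control}\n".encode())
        for sid in sorted(self.segments):
            s = self.segments[sid]
            pts = ";".join(f"{x:.6f},{y:.6f}" for x, y in s.polyline)
            h.update(
                f"S|{sid}|{s.from_node}|{s.to_node}|{s.speed_limit_kmh}|"
                f"{s.road_class}|{int(s.one_way)}|{pts}\n".encode()
            )
        return h.hexdigest()


def segment_travel_time(
    segment: RoadSegment, downstream_control: str, config: ModelConfig
) -> float:
    """Seconds to traverse ``segment`` and enter the downstream intersection.

    Kinematic time at the (factor-scaled) posted limit plus the impedance of
    the control at the node being entered: 0 for an uncontrolled node, the
    stop-sign delay (default 5 s) or the traffic-light delay (default 10 s).
    """
    if segment.speed_limit_kmh <= 0:
        raise ValueError("speed limit must be positive")
    speed_ms = segment.speed_limit_kmh / 3.6 * config.vehicle_speed_factor
    base = segment.length_m / speed_ms
    if downstream_control == CONTROL_NONE:
        delay = 0.0
    elif downstream_control == CONTROL_STOP:
        delay = config.stop_sign_delay_s
    elif downstream_control == CONTROL_LIGHT:
        delay = config.traffic_light_delay_s
    else:
        raise ValueError(f"unknown control {downstream_control!r}")
    return base + delay


def kinematic_time(length_m: float, speed_limit_kmh: float, config: ModelConfig) -> float:
    """Impedance-free travel time for a distance at a posted limit."""
    return length_m / (speed_limit_kmh / 3.6 * config.vehicle_speed_factor)


def load_network(path: str | Path, config: ModelConfig | None = None) -> RoadNetwork:
    """Read a road network from a GeoJSON FeatureCollection.

    LineString features must carry properties ``segment_id``, ``speed_kmh``,
    ``road_class`` and ``one_way`` plus ``from_node``/``to_node`` references.
    Intersection controls come from Point features with ``node_id`` and
    ``control`` in {none, stop, light}; nodes without a Point feature are
    created at the segment endpoints with no control.
    """
    raw = json.loads(Path(path).read_text())
    if raw.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")

    intersections: dict = {}
    seg_features = []
    for feat in raw.get("features", []):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        gtype = geom.get("type")
        if gtype == "Point":
            node_id = str(props.get("node_id"))
            if props.get("node_id") is None:
                raise ValueError("Point feature missing node_id")
            control_raw = str(props.get("control", "none"))
            if control_raw not in _CONTROL_ALIASES:
                raise ValueError(f"node {node_id}: unknown control {control_raw!r}")
            x, y = geom["coordinates"]
            if node_id in intersections:
                raise ValueError(f"duplicate node_id {node_id}")
            intersections[node_id] = Intersection(
                node_id=node_id, x=float(x), y=float(y), control=_CONTROL_ALIASES[control_raw]
            )
        elif gtype == "LineString":
            seg_features.append((geom, props))
        else:
            raise ValueError(f"unsupported geometry type {gtype!r}")

    segments: dict = {}
    for geom, props in seg_features:
        sid = props.get("segment_id")
        if sid is None:
            raise ValueError("LineString feature missing segment_id")
        sid = str(sid)
        if sid in segments:
            raise ValueError(f"duplicate segment_id {sid}")
        if props.get("speed_kmh") is None:
            raise ValueError(f"segment {sid}: missing speed limit (speed_kmh)")
        coords = tuple((float(x), float(y)) for x, y in geom["coordinates"])
        from_node = props.get("from_node")
        to_node = props.get("to_node")
        # implicit nodes for endpoints never declared as Point features
        for key, pt in ((from_node, coords[0]), (to_node, coords[-1])):
            if key is None:
                raise ValueError(f"segment {sid}: missing from_node/to_node reference")
            key = str(key)
            if key not in intersections:
                intersections[key] = Intersection(node_id=key, x=pt[0], y=pt[1])
        segments[sid] = make_segment(
            segment_id=sid,
            from_node=str(from_node),
            to_node=str(to_node),
            polyline=coords,
            speed_limit_kmh=float(props["speed_kmh"]),
            road_class=str(props.get("road_class", "road")),
            one_way=bool(props.get("one_way", False)),
        )

    crs_note = str(raw.get("crs_note", "projected planar CRS, metres"))
    return RoadNetwork(intersections=intersections, segments=segments, crs_note=crs_note)


def write_network(network: RoadNetwork, path: str | Path) -> None:
    """Write a network back to the same GeoJSON dialect ``load_network`` reads."""
    features = []
    for nid in sorted(network.intersections):
        n = network.intersections[nid]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [n.x, n.y]},
                "properties": {"node_id": n.node_id, "control": _CONTROL_FILE_NAMES[n.control]},
            }
        )
    for sid in sorted(network.segments):
        s = network.segments[sid]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(p) for p in s.polyline]},
                "properties": {
                    "segment_id": s.segment_id,
                    "from_node": s.from_node,
                    "to_node": s.to_node,
                    "speed_kmh": s.speed_limit_kmh,
                    "road_class": s.road_class,
                    "one_way": s.one_way,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": network.crs_note,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def filter_roads(network: RoadNetwork, config: ModelConfig) -> RoadNetwork:
    """Drop segments whose road class is excluded; remove orphaned intersections.

    Back roads and logging roads are excluded by default, focusing the model
    on the populated road hierarchy and shrinking the precomputed table.
    """
    keep = {
        sid: seg
        for sid, seg in network.segments.items()
        if seg.road_class not in config.excluded_road_classes
    }
    used_nodes = {seg.from_node for seg in keep.values()} | {seg.to_node for seg in keep.values()}
    nodes = {nid: n for nid, n in network.intersections.items() if nid in used_nodes}
    return RoadNetwork(intersections=nodes, segments=keep, crs_note=network.crs_note)
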