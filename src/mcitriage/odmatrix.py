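"""Precomputed origin–destination driving times.

The expensive step — shortest driving time from every discretized-part
centroid to every hospital — is done once, ahead of the incident, and
stored in a table keyed by (part id, hospital id).  At query time a
location snaps to its nearest part and every hospital's time is a
constant-time lookup, which is what makes sub-second answers possible
during an incident.

Conventions:

* A trip starts at the part centroid and first traverses the residual of
  the origin part; no impedance is charged at the origin point.
* An intersection's impedance is charged when entering it at the end of a
  traversal, and never at the trip's final destination.
* The trip ends at the hospital's snapped location on its part, paying
  only the partial kinematic traversal to that point.
* One-way parts are traversable only in their digitised direction; all
  others both ways.

Times are stored in seconds; minutes (round half up) are an output
formatting choice, so no information is lost in the table itself.

The reference realisation runs one Dijkstra per hospital over the
reversed traversal graph — hospitals are few and centroids many — but any
algorithm yielding the same minima is conformant.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from shapely.geometry import Point
from shapely.strtree import STRtree

from .config import ModelConfig
from .discretize import DiscretizedLayer
from .network import CONTROL_NONE, RoadNetwork, kinematic_time


class _Unreachable:
    """Distinguished result for a centroid with no path to a hospital."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNREACHABLE"


UNREACHABLE = _Unreachable()


def round_minutes(seconds: float) -> int:
    """Whole minutes, round half up (770 s -> 13 min, 750 s -> 13 min)."""
    return int(math.floor(seconds / 60.0 + 0.5))


# ---------------------------------------------------------------------------
# snapping


def _layer_geometries(layer: DiscretizedLayer):
    """Sorted (dseg_id, LineString) pairs plus an STRtree, cached on the layer."""
    cache = getattr(layer, "_snap_cache", None)
    if cache is not None and cache[0] == len(layer.parts):
        return cache[1], cache[2]
    ids = sorted(layer.parts)
    geoms = [layer.parts[d].geometry for d in ids]
    tree = STRtree(geoms)
    layer._snap_cache = (len(layer.parts), (ids, geoms), tree)
    return (ids, geoms), tree


def snap_point_to_dseg(point, layer: DiscretizedLayer) -> str:
    """Nearest discretized part to an (x, y) point; ties to the lowest part id."""
    if not layer.parts:
        raise ValueError("cannot snap to an empty discretized layer")
    (ids, geoms), tree = _layer_geometries(layer)
    p = Point(point)
    idx = tree.query_nearest(p, all_matches=True)
    best_ids = sorted(ids[i] for i in idx)
    if len(best_ids) == 1:
        return best_ids[0]
    # exact tie-break on distance then id
    best = None
    best_d = math.inf
    for i in sorted(idx):
        d = geoms[i].distance(p)
        if d < best_d or (d == best_d and (best is None or ids[i] < best)):
            best, best_d = ids[i], d
    return best


# ---------------------------------------------------------------------------
# traversal graph


def build_graph(network: RoadNetwork, layer: DiscretizedLayer, config: ModelConfig):
    """Directed traversal graph over discretized parts.

    Nodes are original intersections plus synthetic split nodes; each
    allowed traversal direction of a part contributes one edge weighted
    kinematic time + impedance of the node being entered (split nodes
    carry no control).
    """
    g = nx.MultiDiGraph()

    def delay_at(node_id: str) -> float:
        inter = network.intersections.get(node_id)
        if inter is None or inter.control == CONTROL_NONE:
            return 0.0
        if inter.control == "stop_sign":
            return config.stop_sign_delay_s
        return config.traffic_light_delay_s

    for dseg_id in sorted(layer.parts):
        p = layer.parts[dseg_id]
        base = kinematic_time(p.length_m, p.speed_limit_kmh, config)
        g.add_edge(p.start_node, p.end_node, key=dseg_id, weight=base + delay_at(p.end_node))
        if not p.one_way:
            g.add_edge(p.end_node, p.start_node, key=dseg_id, weight=base + delay_at(p.start_node))
    return g


def _node_delays(network: RoadNetwork, config: ModelConfig) -> dict:
    delays = {}
    for nid, inter in network.intersections.items():
        if inter.control == "stop_sign":
            delays[nid] = config.stop_sign_delay_s
        elif inter.control == "traffic_light":
            delays[nid] = config.traffic_light_delay_s
        else:
            delays[nid] = 0.0
    return delays


# ---------------------------------------------------------------------------
# the driving-time table


@dataclass
class DrivingTimeTable:
    """(part id, hospital id) -> shortest driving time in seconds.

    Unreachable pairs are stored explicitly (``None`` internally, a
    ``reachable`` flag on disk) rather than as a sentinel number.
    ``metadata`` carries the config snapshot and the network fingerprint
    so a stale table cannot silently be joined to a different network.
    """

    entries: dict = field(default_factory=dict)  # (dseg_id, hospital_id) -> float | None
    metadata: dict = field(default_factory=dict)

    def hospitals(self) -> list:
        return sorted({h for _, h in self.entries})

    def __len__(self) -> int:
        return len(self.entries)


def hospital_position_on_part(hospital, layer: DiscretizedLayer) -> float:
    """Arc-length position of the hospital's snapped point along its part."""
    part = layer.parts[hospital.snapped_dseg]
    return part.geometry.project(Point(hospital.x, hospital.y))


def precompute_od(
    network: RoadNetwork,
    layer: DiscretizedLayer,
    registry,
    config: ModelConfig,
) -> DrivingTimeTable:
    """Shortest driving time from every part centroid to every hospital.

    One reversed-graph Dijkstra per hospital; the per-centroid time is then
    assembled analytically from the origin part's residual traversals.
    Disconnected centroids are flagged unreachable, not raised.
    """
    for h in registry:
        if h.snapped_dseg is None:
            raise ValueError(f"hospital {h.hospital_id} is not snapped to the network")

    graph = build_graph(network, layer, config)
    reverse = graph.reverse(copy=True)
    delays = _node_delays(network, config)

    table = DrivingTimeTable(
        metadata={
            "config": config.to_dict(),
            "network_fingerprint": network.fingerprint(),
            "n_parts": len(layer.parts),
            "n_hospitals": len(registry),
        }
    )

    part_ids = sorted(layer.parts)
    for h in registry:
        hpart = layer.parts[h.snapped_dseg]
        s_h = hospital_position_on_part(h, layer)
        hnode = ("__hospital__", h.hospital_id)
        # entry edges: partial traversal of the hospital part to the snapped
        # point, no impedance at the destination
        reverse.add_edge(
            hnode, hpart.start_node,
            weight=kinematic_time(s_h, hpart.speed_limit_kmh, config),
        )
        if not hpart.one_way:
            reverse.add_edge(
                hnode, hpart.end_node,
                weight=kinematic_time(hpart.length_m - s_h, hpart.speed_limit_kmh, config),
            )
        dist = nx.single_source_dijkstra_path_length(reverse, hnode, weight="weight")

        for dseg_id in part_ids:
            p = layer.parts[dseg_id]
            s_c = p.length_m / 2.0
            candidates = []
            if dseg_id == h.snapped_dseg:
                if s_h >= s_c:
                    candidates.append(kinematic_time(s_h - s_c, p.speed_limit_kmh, config))
                elif not p.one_way:
                    candidates.append(kinematic_time(s_c - s_h, p.speed_limit_kmh, config))
            d_end = dist.get(p.end_node)
            if d_end is not None:
                candidates.append(
                    kinematic_time(p.length_m - s_c, p.speed_limit_kmh, config)
                    + delays.get(p.end_node, 0.0)
                    + d_end
                )
            if not p.one_way:
                d_start = dist.get(p.start_node)
                if d_start is not None:
                    candidates.append(
                        kinematic_time(s_c, p.speed_limit_kmh, config)
                        + delays.get(p.start_node, 0.0)
                        + d_start
                    )
            table.entries[(dseg_id, h.hospital_id)] = min(candidates) if candidates else None

        reverse.remove_node(hnode)

    return table


def single_pair_time(
    network: RoadNetwork,
    layer: DiscretizedLayer,
    hospital,
    dseg_id: str,
    config: ModelConfig,
):
    """On-demand shortest time for one (centroid, hospital) pair.

    Forward Dijkstra from a virtual origin node — the mirror image of the
    batch routine's reversed search — used to spot-check table entries.
    """
    graph = build_graph(network, layer, config)
    delays = _node_delays(network, config)
    p = layer.parts[dseg_id]
    hpart = layer.parts[hospital.snapped_dseg]
    s_h = hospital_position_on_part(hospital, layer)
    s_c = p.length_m / 2.0

    origin, dest = "__origin__", "__dest__"
    graph.add_edge(
        origin, p.end_node,
        weight=kinematic_time(p.length_m - s_c, p.speed_limit_kmh, config)
        + delays.get(p.end_node, 0.0),
    )
    if not p.one_way:
        graph.add_edge(
            origin, p.start_node,
            weight=kinematic_time(s_c, p.speed_limit_kmh, config)
            + delays.get(p.start_node, 0.0),
        )
    graph.add_edge(
        hpart.start_node, dest,
        weight=kinematic_time(s_h, hpart.speed_limit_kmh, config),
    )
    if not hpart.one_way:
        graph.add_edge(
            hpart.end_node, dest,
            weight=kinematic_time(hpart.length_m - s_h, hpart.speed_limit_kmh, config),
        )
    if dseg_id == hospital.snapped_dseg:
        if s_h >= s_c:
            graph.add_edge(
                origin, dest, weight=kinematic_time(s_h - s_c, p.speed_limit_kmh, config)
            )
        elif not p.one_way:
            graph.add_edge(
                origin, dest, weight=kinematic_time(s_c - s_h, p.speed_limit_kmh, config)
            )
    try:
        return nx.dijkstra_path_length(graph, origin, dest, weight="weight")
    except nx.NetworkXNoPath:
        return None


def lookup_time(table: DrivingTimeTable, dseg_id: str, hospital_id: str, rounding: bool = False):
    """Stored driving time; whole minutes (half up) when ``rounding``.

    Unknown ids raise ``KeyError``; an unreachable pair returns the
    distinguished ``UNREACHABLE`` value.
    """
    key = (dseg_id, hospital_id)
    if key not in table.entries:
        raise KeyError(f"no table entry for part {dseg_id!r}, hospital {hospital_id!r}")
    seconds = table.entries[key]
    if seconds is None:
        return UNREACHABLE
    return round_minutes(seconds) if rounding else seconds


# ---------------------------------------------------------------------------
# persistence: CSV entries + JSON metadata sidecar (diff-able, language-neutral)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def save_table(table: DrivingTimeTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dseg_id", "hospital_id", "seconds", "reachable"])
        for (dseg_id, hospital_id) in sorted(table.entries):
            sec = table.entries[(dseg_id, hospital_id)]
            writer.writerow(
                [dseg_id, hospital_id, "" if sec is None else repr(sec), int(sec is not None)]
            )
    _sidecar(path).write_text(json.dumps(table.metadata, indent=1, sort_keys=True))


def load_table(
    path: str | Path,
    network: RoadNetwork | None = None,
    force: bool = False,
) -> DrivingTimeTable:
    """Load a saved table; refuse one built for a different network.

    Passing ``network`` checks its fingerprint against the sidecar; a
    mismatch is an error unless ``force`` is set.
    """
    path = Path(path)
    meta_path = _sidecar(path)
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if network is not None and not force:
        expected = metadata.get("network_fingerprint")
        actual = network.fingerprint()
        if expected != actual:
            raise ValueError(
                f"table {path} was built for network fingerprint {expected}, "
                f"but the loaded network has {actual}; pass force=True to override"
            )
    entries: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            reachable = bool(int(row["reachable"]))
            entries[(row["dseg_id"], row["hospital_id"])] = (
                float(row["seconds"]) if reachable else None
            )
    return DrivingTimeTable(entries=entries, metadata=metadata)
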