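"""Independent oracles for shortest driving times.

These deliberately avoid the package's graph-building and Dijkstra code
paths: exhaustive simple-path enumeration for small networks, and the
Manhattan closed form for uniform grid cities.  Both implement the same
travel-time semantics from first principles — kinematic time at the
posted limit, impedance charged on entering a controlled intersection,
no impedance at the origin point or the final destination.
"""

from __future__ import annotations

from mcitriage.odmatrix import hospital_position_on_part
from mcitriage.synthcity import parse_node_id


def _kin(length_m, speed_kmh, cfg):
    return length_m / (speed_kmh / 3.6 * cfg.vehicle_speed_factor)


def _delay(network, node_id, cfg):
    inter = network.intersections.get(node_id)
    if inter is None or inter.control == "none":
        return 0.0
    return cfg.stop_sign_delay_s if inter.control == "stop_sign" else cfg.traffic_light_delay_s


def brute_force_time(network, layer, hospital, dseg_id, cfg):
    """Exhaustive enumeration of simple node paths; None if unreachable.

    Only usable on tiny networks (the path count is exponential).
    """
    parts = layer.parts
    o = parts[dseg_id]
    hpart = parts[hospital.snapped_dseg]
    s_h = hospital_position_on_part(hospital, layer)
    s_c = o.length_m / 2.0

    # directed traversals: u -> v with kinematic cost
    edges = {}
    for p in parts.values():
        base = _kin(p.length_m, p.speed_limit_kmh, cfg)
        edges.setdefault(p.start_node, []).append((p.end_node, base))
        if not p.one_way:
            edges.setdefault(p.end_node, []).append((p.start_node, base))

    # ways to leave the origin centroid: (first node, cost incl. its delay)
    starts = [(o.end_node, _kin(o.length_m - s_c, o.speed_limit_kmh, cfg)
               + _delay(network, o.end_node, cfg))]
    if not o.one_way:
        starts.append((o.start_node, _kin(s_c, o.speed_limit_kmh, cfg)
                       + _delay(network, o.start_node, cfg)))

    # ways to reach the hospital point from a node (no delay at destination)
    finishes = {hpart.start_node: _kin(s_h, hpart.speed_limit_kmh, cfg)}
    if not hpart.one_way:
        cost = _kin(hpart.length_m - s_h, hpart.speed_limit_kmh, cfg)
        finishes[hpart.end_node] = min(finishes.get(hpart.end_node, float("inf")), cost)

    best = [float("inf")]
    if dseg_id == hospital.snapped_dseg:
        if s_h >= s_c:
            best[0] = _kin(s_h - s_c, o.speed_limit_kmh, cfg)
        elif not o.one_way:
            best[0] = _kin(s_c - s_h, o.speed_limit_kmh, cfg)

    def dfs(node, cost, visited):
        if cost >= best[0]:
            return
        if node in finishes:
            total = cost + finishes[node]
            if total < best[0]:
                best[0] = total
        for nxt, kin in edges.get(node, []):
            if nxt in visited:
                continue
            dfs(nxt, cost + kin + _delay(network, nxt, cfg), visited | {nxt})

    for node, cost in starts:
        dfs(node, cost, {node})

    return None if best[0] == float("inf") else best[0]


def manhattan_time(spec, layer, hospital, dseg_id, cfg):
    """Closed-form time on a uniform-speed, zero-control, straight-edge grid."""
    speed = spec.speed_set_kmh[0]
    block = _kin(spec.spacing_m, speed, cfg)
    parts = layer.parts
    o = parts[dseg_id]
    hpart = parts[hospital.snapped_dseg]
    s_h = hospital_position_on_part(hospital, layer)
    s_c = o.length_m / 2.0

    def steps(nid_a, nid_b):
        (r0, c0), (r1, c1) = parse_node_id(nid_a), parse_node_id(nid_b)
        return abs(r0 - r1) + abs(c0 - c1)

    exits = [(o.end_node, _kin(o.length_m - s_c, speed, cfg)),
             (o.start_node, _kin(s_c, speed, cfg))]
    entries = [(hpart.start_node, _kin(s_h, speed, cfg)),
               (hpart.end_node, _kin(hpart.length_m - s_h, speed, cfg))]
    best = min(res + steps(a, b) * block + ent
               for a, res in exits for b, ent in entries)
    if dseg_id == hospital.snapped_dseg:
        best = min(best, _kin(abs(s_h - s_c), speed, cfg))
    return best
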