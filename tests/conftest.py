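"""Shared fixtures: hand-built toy networks and seeded grid cities."""

from __future__ import annotations

import pytest

from mcitriage import (
    CitySpec,
    Hospital,
    HospitalRegistry,
    Intersection,
    ModelConfig,
    RoadNetwork,
    discretize_network,
    generate_city,
    make_segment,
    precompute_od,
    snap_hospitals,
)


def build_network(nodes, edges, controls=None):
    """Toy-network builder.

    ``nodes``: {node_id: (x, y)}; ``edges``: (segment_id, u, v, speed_kmh)
    or with extra road_class / one_way entries; straight polylines.
    """
    controls = controls or {}
    intersections = {
        nid: Intersection(node_id=nid, x=xy[0], y=xy[1], control=controls.get(nid, "none"))
        for nid, xy in nodes.items()
    }
    segments = {}
    for edge in edges:
        sid, u, v, speed = edge[:4]
        road_class = edge[4] if len(edge) > 4 else "road"
        one_way = edge[5] if len(edge) > 5 else False
        segments[sid] = make_segment(
            segment_id=sid, from_node=u, to_node=v,
            polyline=[nodes[u], nodes[v]], speed_limit_kmh=speed,
            road_class=road_class, one_way=one_way,
        )
    return RoadNetwork(intersections=intersections, segments=segments)


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def single_segment_city(config):
    """One 200 m segment at 36 km/h with a hospital at the far end."""
    net = build_network({"a": (0.0, 0.0), "b": (200.0, 0.0)}, [("s1", "a", "b", 36.0)])
    layer = discretize_network(net, config)
    registry = HospitalRegistry()
    registry.add(Hospital(hospital_id="h1", name="End", x=200.0, y=0.0,
                          trauma_level=1, capacity=10))
    snap_hospitals(registry, layer)
    return net, layer, registry


@pytest.fixture(scope="session")
def grid_city_10():
    """Seeded default 10×10 city with controls, mixed speeds and long edges."""
    cfg = ModelConfig()
    net, registry = generate_city(CitySpec(seed=42))
    layer = discretize_network(net, cfg)
    snap_hospitals(registry, layer)
    table = precompute_od(net, layer, registry, cfg)
    return cfg, net, layer, registry, table


@pytest.fixture(scope="session")
def uniform_grid_city():
    """Uniform-speed, zero-control 8×8 grid: Manhattan closed form applies."""
    cfg = ModelConfig()
    spec = CitySpec(rows=8, cols=8, spacing_m=200.0, speed_set_kmh=(36.0,),
                    p_stop=0.0, p_light=0.0, long_segment_fraction=0.0,
                    n_hospitals=4, seed=3)
    net, registry = generate_city(spec)
    layer = discretize_network(net, cfg)
    snap_hospitals(registry, layer)
    table = precompute_od(net, layer, registry, cfg)
    return cfg, spec, net, layer, registry, table
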