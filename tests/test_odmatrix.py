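"""Precomputed driving-time table: oracles, lookups, snapping, persistence."""

import math

import numpy as np
import pytest

from mcitriage import (
    CitySpec,
    Hospital,
    HospitalRegistry,
    ModelConfig,
    UNREACHABLE,
    discretize_network,
    generate_city,
    load_table,
    lookup_time,
    precompute_od,
    round_minutes,
    save_table,
    snap_hospitals,
    snap_point_to_dseg,
)
from mcitriage.odmatrix import single_pair_time

from conftest import build_network
from oracles import brute_force_time, manhattan_time


def random_small_network(seed, max_nodes=8):
    """Connected random network on <= max_nodes nodes with mixed attributes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    coords = rng.uniform(0, 600, size=(n, 2))
    controls = {}
    nodes = {}
    for i in range(n):
        nodes[f"v{i}"] = (float(coords[i, 0]), float(coords[i, 1]))
        u = rng.random()
        controls[f"v{i}"] = "stop_sign" if u < 0.25 else ("traffic_light" if u < 0.45 else "none")
    edges = []
    # random spanning tree keeps it connected, then a few extra chords
    order = rng.permutation(n)
    for k in range(1, n):
        a, b = order[k], order[int(rng.integers(k))]
        edges.append((a, b))
    for _ in range(int(rng.integers(0, n))):
        a, b = rng.integers(n), rng.integers(n)
        if a != b and (a, b) not in edges and (b, a) not in edges:
            edges.append((int(a), int(b)))
    spec_edges = []
    for idx, (a, b) in enumerate(edges):
        speed = float(rng.choice([30.0, 50.0, 60.0, 80.0]))
        one_way = bool(rng.random() < 0.15)
        spec_edges.append((f"e{idx}", f"v{a}", f"v{b}", speed, "road", one_way))
    return build_network(nodes, spec_edges, controls), rng


def place_hospital(layer, rng):
    ids = sorted(layer.parts)
    part = layer.parts[ids[int(rng.integers(len(ids)))]]
    pt = part.geometry.interpolate(float(rng.random()), normalized=True)
    h = Hospital(hospital_id="h", name="H", x=pt.x, y=pt.y, trauma_level=1, capacity=5)
    reg = HospitalRegistry()
    reg.add(h)
    return reg, h


class TestShortestTimeOracle:
    def test_single_segment_midpoint_origin(self, config, single_segment_city):
        # hospital at the far end of a 200 m, 36 km/h segment: the centroid
        # sits 100 m away, so the stored time is the half-segment traversal
        net, layer, registry = single_segment_city
        table = precompute_od(net, layer, registry, config)
        assert table.entries[("s1:0", "h1")] == pytest.approx(10.0)

    def test_six_node_graph_matches_path_enumeration(self, config):
        net, rng = random_small_network(seed=123)
        layer = discretize_network(net, config)
        registry, hospital = place_hospital(layer, rng)
        snap_hospitals(registry, layer)
        table = precompute_od(net, layer, registry, config)
        for dseg_id in layer.parts:
            expected = brute_force_time(net, layer, hospital, dseg_id, config)
            got = table.entries[(dseg_id, "h")]
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_graphs_match_enumeration(self, seed, config):
        net, rng = random_small_network(seed)
        layer = discretize_network(net, config)
        registry, hospital = place_hospital(layer, rng)
        snap_hospitals(registry, layer)
        table = precompute_od(net, layer, registry, config)
        for dseg_id in sorted(layer.parts):
            expected = brute_force_time(net, layer, hospital, dseg_id, config)
            got = table.entries[(dseg_id, "h")]
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, rel=1e-9)

    def test_uniform_grid_matches_manhattan_closed_form(self, uniform_grid_city):
        cfg, spec, net, layer, registry, table = uniform_grid_city
        for h in registry:
            for dseg_id in layer.parts:
                expected = manhattan_time(spec, layer, h, dseg_id, cfg)
                assert table.entries[(dseg_id, h.hospital_id)] == pytest.approx(
                    expected, rel=1e-9
                )

    def test_table_agrees_with_on_demand_single_pairs(self, grid_city_10):
        cfg, net, layer, registry, table = grid_city_10
        rng = np.random.default_rng(9)
        ids = sorted(layer.parts)
        hs = list(registry)
        for _ in range(100):
            dseg_id = ids[int(rng.integers(len(ids)))]
            h = hs[int(rng.integers(len(hs)))]
            fresh = single_pair_time(net, layer, h, dseg_id, cfg)
            assert table.entries[(dseg_id, h.hospital_id)] == pytest.approx(fresh, rel=1e-9)

    def test_unsnapped_hospital_rejected(self, config, single_segment_city):
        net, layer, _ = single_segment_city
        reg = HospitalRegistry()
        reg.add(Hospital(hospital_id="x", name="X", x=0, y=0, trauma_level=1, capacity=1))
        with pytest.raises(ValueError, match="not snapped"):
            precompute_od(net, layer, reg, config)

    def test_disconnected_centroid_flagged_unreachable(self, config):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (1000.0, 0.0), "d": (1100.0, 0.0)}
        net = build_network(nodes, [("s1", "a", "b", 50.0), ("s2", "c", "d", 50.0)])
        layer = discretize_network(net, config)
        reg = HospitalRegistry()
        reg.add(Hospital(hospital_id="h", name="H", x=100, y=0, trauma_level=1, capacity=1))
        snap_hospitals(reg, layer)
        table = precompute_od(net, layer, reg, config)
        assert table.entries[("s2:0", "h")] is None
        assert lookup_time(table, "s2:0", "h") is UNREACHABLE


class TestMonotonicity:
    def test_adding_traffic_light_never_decreases_entries(self, config):
        net, registry = generate_city(CitySpec(rows=5, cols=5, seed=21, p_stop=0.0, p_light=0.0))
        layer = discretize_network(net, config)
        snap_hospitals(registry, layer)
        base = precompute_od(net, layer, registry, config)
        lit = net.with_control("n2_2", "traffic_light")
        layer2 = discretize_network(lit, config)
        snap_hospitals(registry, layer2)
        after = precompute_od(lit, layer2, registry, config)
        for key, before in base.entries.items():
            assert after.entries[key] >= before - 1e-9

    def test_faster_vehicle_never_increases_entries(self, single_segment_city, config):
        net, layer, registry = single_segment_city
        slow = precompute_od(net, layer, registry, config)
        fast = precompute_od(net, layer, registry, ModelConfig(vehicle_speed_factor=1.5))
        for key in slow.entries:
            assert fast.entries[key] <= slow.entries[key] + 1e-9

    def test_forward_equals_reverse_without_impedances(self):
        cfg = ModelConfig(stop_sign_delay_s=0.0, traffic_light_delay_s=0.0)
        import dataclasses

        net, rng = random_small_network(seed=77)
        # make fully bidirectional
        segs = {sid: dataclasses.replace(s, one_way=False) for sid, s in net.segments.items()}
        net = type(net)(intersections=net.intersections, segments=segs)
        layer = discretize_network(net, cfg)
        registry, hospital = place_hospital(layer, rng)
        snap_hospitals(registry, layer)
        table = precompute_od(net, layer, registry, cfg)
        for dseg_id in sorted(layer.parts)[:10]:
            forward = single_pair_time(net, layer, hospital, dseg_id, cfg)
            got = table.entries[(dseg_id, "h")]
            if forward is None:
                assert got is None
            else:
                assert got == pytest.approx(forward, rel=1e-9)


class TestLookup:
    def _table(self, single_segment_city, config, seconds):
        net, layer, registry = single_segment_city
        table = precompute_od(net, layer, registry, config)
        table.entries[("s1:0", "h1")] = seconds
        return table

    def test_exact_minutes(self, single_segment_city, config):
        table = self._table(single_segment_city, config, 780.0)
        assert lookup_time(table, "s1:0", "h1", rounding=True) == 13

    def test_round_half_up(self, single_segment_city, config):
        table = self._table(single_segment_city, config, 770.0)
        assert lookup_time(table, "s1:0", "h1", rounding=True) == 13
        assert round_minutes(750.0) == 13  # exactly half a minute rounds up
        assert round_minutes(749.9) == 12

    def test_unknown_id_raises(self, single_segment_city, config):
        table = self._table(single_segment_city, config, 100.0)
        with pytest.raises(KeyError):
            lookup_time(table, "nope", "h1")


class TestSnapping:
    def test_point_on_polyline_snaps_to_it(self, grid_city_10):
        _, _, layer, _, _ = grid_city_10
        part = layer.parts[sorted(layer.parts)[17]]
        pt = part.geometry.interpolate(0.3, normalized=True)
        snapped = snap_point_to_dseg((pt.x, pt.y), layer)
        assert layer.parts[snapped].geometry.distance(pt) <= 1e-9

    def test_equidistant_tie_takes_lowest_id(self, config):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (0.0, 100.0), "d": (100.0, 100.0)}
        net = build_network(nodes, [("sA", "a", "b", 50.0), ("sB", "c", "d", 50.0)])
        layer = discretize_network(net, config)
        # midway between the two parallel roads
        assert snap_point_to_dseg((50.0, 50.0), layer) == "sA:0"

    def test_matches_brute_force_nearest_scan(self, grid_city_10):
        _, _, layer, _, _ = grid_city_10
        rng = np.random.default_rng(4)
        from shapely.geometry import Point

        for _ in range(50):
            p = Point(float(rng.uniform(-100, 2000)), float(rng.uniform(-100, 2000)))
            best = min(
                sorted(layer.parts),
                key=lambda d: (layer.parts[d].geometry.distance(p), d),
            )
            assert snap_point_to_dseg((p.x, p.y), layer) == best

    def test_empty_layer_rejected(self):
        from mcitriage import DiscretizedLayer

        with pytest.raises(ValueError):
            snap_point_to_dseg((0, 0), DiscretizedLayer())


class TestPersistence:
    def test_round_trip_identical(self, tmp_path, grid_city_10):
        _, net, _, _, table = grid_city_10
        path = tmp_path / "table.csv"
        save_table(table, path)
        loaded = load_table(path, network=net)
        assert loaded.entries == table.entries
        assert loaded.metadata["network_fingerprint"] == net.fingerprint()

    def test_fingerprint_mismatch_refused(self, tmp_path, grid_city_10, config):
        _, _, _, _, table = grid_city_10
        other, _ = generate_city(CitySpec(rows=3, cols=3, seed=99))
        path = tmp_path / "table.csv"
        save_table(table, path)
        with pytest.raises(ValueError, match="fingerprint"):
            load_table(path, network=other)
        # force overrides
        assert len(load_table(path, network=other, force=True).entries) == len(table.entries)

    def test_empty_table_round_trips(self, tmp_path):
        from mcitriage import DrivingTimeTable

        path = tmp_path / "empty.csv"
        save_table(DrivingTimeTable(metadata={"note": "empty"}), path)
        loaded = load_table(path)
        assert loaded.entries == {} and loaded.metadata == {"note": "empty"}

    def test_unreachable_flag_survives_round_trip(self, tmp_path, config):
        from mcitriage import DrivingTimeTable

        table = DrivingTimeTable(entries={("a", "h"): 12.5, ("b", "h"): None})
        path = tmp_path / "t.csv"
        save_table(table, path)
        assert load_table(path).entries == {("a", "h"): 12.5, ("b", "h"): None}
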