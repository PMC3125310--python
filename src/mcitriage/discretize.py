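"""Discretization of road segments to a maximum length.

Long segments are split into equal-arc-length parts so that no part
exceeds the configured maximum (200 m by default); segments at or below
the maximum pass through unchanged.  Each part is then represented by its
centroid — the point at half the part's arc length, on the line itself —
which serves as the travel-time origin for that part in the precomputed
driving-time table.  The centroid-ID-to-parent-segment mapping is kept
both ways so a user-selected segment resolves to its table rows.

Part ids are formed deterministically from the parent id and the part
ordinal, so rebuilt tables are stable across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from shapely.geometry import LineString
from shapely.ops import substring

from .config import ModelConfig
from .network import RoadNetwork, RoadSegment


@dataclass(frozen=True)
class DiscretizedSegment:
    dseg_id: str
    parent_segment_id: str
    polyline: tuple
    length_m: float
    centroid: tuple  # (x, y) at half arc length
    part_index: int
    # graph endpoints: original intersection ids for outer ends,
    # synthetic split-node ids between consecutive parts
    start_node: str
    end_node: str
    speed_limit_kmh: float
    one_way: bool

    @property
    def geometry(self) -> LineString:
        return LineString(self.polyline)


def _part_id(parent_id: str, index: int) -> str:
    return f"{parent_id}:{index}"


def _split_node_id(parent_id: str, boundary: int) -> str:
    return f"{parent_id}:n{boundary}"


def centroid_of(polyline_or_dseg) -> tuple:
    """Point at half the arc length of a polyline (not the chord midpoint)."""
    if isinstance(polyline_or_dseg, DiscretizedSegment):
        line = polyline_or_dseg.geometry
    elif isinstance(polyline_or_dseg, LineString):
        line = polyline_or_dseg
    else:
        line = LineString(polyline_or_dseg)
    p = line.interpolate(0.5, normalized=True)
    return (p.x, p.y)


def split_segment(segment: RoadSegment, config: ModelConfig) -> list:
    """Split one segment into equal-length parts no longer than the maximum.

    A segment at or below ``max_segment_length_m`` yields a single part
    identical to the parent; a longer one is cut into
    ``ceil(length / max)`` equal-arc-length pieces whose geometries
    concatenate back to the parent polyline.
    """
    line = segment.geometry
    total = line.length
    max_len = config.max_segment_length_m
    k = 1 if total <= max_len else math.ceil(total / max_len)
    parts = []
    for i in range(k):
        if k == 1:
            piece = line
        else:
            piece = substring(line, i * total / k, (i + 1) * total / k)
        coords = tuple((p[0], p[1]) for p in piece.coords)
        start = segment.from_node if i == 0 else _split_node_id(segment.segment_id, i)
        end = segment.to_node if i == k - 1 else _split_node_id(segment.segment_id, i + 1)
        parts.append(
            DiscretizedSegment(
                dseg_id=_part_id(segment.segment_id, i),
                parent_segment_id=segment.segment_id,
                polyline=coords,
                length_m=piece.length,
                centroid=centroid_of(piece),
                part_index=i,
                start_node=start,
                end_node=end,
                speed_limit_kmh=segment.speed_limit_kmh,
                one_way=segment.one_way,
            )
        )
    return parts


@dataclass
class DiscretizedLayer:
    """All parts of a network plus the part-id ↔ parent-id index."""

    parts: dict = field(default_factory=dict)  # dseg_id -> DiscretizedSegment
    by_parent: dict = field(default_factory=dict)  # parent_segment_id -> [dseg_id, ...]

    def parent_of(self, dseg_id: str) -> str:
        return self.parts[dseg_id].parent_segment_id

    def parts_of(self, parent_segment_id: str) -> list:
        return [self.parts[d] for d in self.by_parent[parent_segment_id]]

    def __len__(self) -> int:
        return len(self.parts)


def discretize_network(network: RoadNetwork, config: ModelConfig) -> DiscretizedLayer:
    """Discretize every segment of a (filtered) network."""
    layer = DiscretizedLayer()
    for sid in sorted(network.segments):
        parts = split_segment(network.segments[sid], config)
        layer.by_parent[sid] = [p.dseg_id for p in parts]
        for p in parts:
            layer.parts[p.dseg_id] = p
    return layer


def write_layer(layer: DiscretizedLayer, path: str | Path) -> None:
    """Write the discretized layer as GeoJSON (inspection / external mapping)."""
    features = []
    for dseg_id in sorted(layer.parts):
        p = layer.parts[dseg_id]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in p.polyline]},
                "properties": {
                    "dseg_id": p.dseg_id,
                    "parent_segment_id": p.parent_segment_id,
                    "part_index": p.part_index,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1, sort_keys=True)
    )
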