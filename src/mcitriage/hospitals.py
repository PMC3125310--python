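"""Hospital registry: location, trauma level, capacity, inclusion.

Hospitals are point features geocoded at the emergency-room access (not
the campus centroid — large hospitals span blocks and the ER entrance is
what matters for driving time).  The trauma level follows the Canadian
designation 1 (tertiary/academic) through 4 (secondary, bypass
protocols); level 9 marks a non-trauma hospital, kept in the registry
because it is the fallback when trauma centres are overloaded.

``capacity`` is the number of critically injured patients the hospital
can accept in the current incident; it is session-editable and is drawn
down as patients are allocated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

TRAUMA_LEVELS = frozenset({1, 2, 3, 4, 9})
NON_TRAUMA_LEVEL = 9


@dataclass
class Hospital:
    hospital_id: str
    name: str
    x: float
    y: float
    trauma_level: int
    capacity: int
    services: str = ""
    included: bool = True
    snapped_dseg: str | None = None

    def __post_init__(self) -> None:
        if self.trauma_level not in TRAUMA_LEVELS:
            raise ValueError(
                f"hospital {self.hospital_id}: trauma_level {self.trauma_level} "
                f"not in {sorted(TRAUMA_LEVELS)}"
            )
        if self.capacity < 0:
            raise ValueError(f"hospital {self.hospital_id}: capacity must be >= 0")


@dataclass
class HospitalRegistry:
    hospitals: dict = field(default_factory=dict)  # hospital_id -> Hospital

    def __len__(self) -> int:
        return len(self.hospitals)

    def __iter__(self):
        return iter(sorted(self.hospitals.values(), key=lambda h: h.hospital_id))

    def __getitem__(self, hospital_id: str) -> Hospital:
        return self.hospitals[hospital_id]

    def add(self, hospital: Hospital) -> None:
        if hospital.hospital_id in self.hospitals:
            raise ValueError(f"duplicate hospital id {hospital.hospital_id}")
        self.hospitals[hospital.hospital_id] = hospital

    def included(self) -> list:
        return [h for h in self if h.included]

    def set_capacity(self, hospital_id: str, new_capacity: int) -> None:
        if new_capacity < 0:
            raise ValueError("capacity cannot be negative")
        self.hospitals[hospital_id].capacity = int(new_capacity)

    def set_included(self, hospital_id: str, flag: bool) -> None:
        self.hospitals[hospital_id].included = bool(flag)


def load_hospitals(path: str | Path) -> HospitalRegistry:
    """Read the registry from CSV: id,name,x,y,trauma_level,capacity[,services].

    Coordinates are in the same projected planar CRS as the road network.
    Rows with a trauma level outside {1,2,3,4,9} or a negative capacity are
    hard errors naming the offending row.
    """
    registry = HospitalRegistry()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "name", "x", "y", "trauma_level", "capacity"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: hospital CSV must have columns {sorted(required)}")
        for rowno, row in enumerate(reader, start=2):
            try:
                hospital = Hospital(
                    hospital_id=row["id"].strip(),
                    name=row["name"].strip(),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    trauma_level=int(row["trauma_level"]),
                    capacity=int(row["capacity"]),
                    services=(row.get("services") or "").strip(),
                )
            except ValueError as exc:
                raise ValueError(f"{path} row {rowno}: {exc}") from exc
            registry.add(hospital)
    return registry


def save_hospitals(registry: HospitalRegistry, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "x", "y", "trauma_level", "capacity", "services"])
        for h in registry:
            writer.writerow(
                [h.hospital_id, h.name, repr(h.x), repr(h.y), h.trauma_level, h.capacity, h.services]
            )


def snap_hospitals(registry: HospitalRegistry, layer) -> HospitalRegistry:
    """Assign each hospital the nearest discretized part (in place).

    Uses the same nearest-part rule as point snapping elsewhere: minimal
    Euclidean distance to the part polyline, ties to the lowest part id.
    """
    from .odmatrix import snap_point_to_dseg

    for h in registry:
        h.snapped_dseg = snap_point_to_dseg((h.x, h.y), layer)
    return registry
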