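"""Decision support at the incident: ranked hospitals and patient allocation.

Given an incident location, ``query_mci`` snaps it to the road network
and returns every included hospital with its precomputed driving time,
ranked nearest first.  Non-trauma hospitals (level 9) stay in the list —
they are the fallback when the trauma system is overloaded.

``allocate_patients`` turns the ranked list into a concrete plan for a
number of critically injured patients using a greedy policy within
trauma-priority tiers: major trauma centres (levels 1–2) first, then
initial-care/secondary centres (levels 3–4), then non-trauma hospitals
(level 9).  Each patient in turn goes to the closest hospital with
residual capacity in the highest tier that still has any; capacities are
drawn down as patients are assigned, and patients beyond total system
capacity are reported as unassigned rather than forced.  Only a full
hospital (capacity 0) diverts patients; "busy" states are not modelled.
The tiering is a parameter, so alternative policies can be examined.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from .hospitals import HospitalRegistry
from .odmatrix import UNREACHABLE, DrivingTimeTable, lookup_time, snap_point_to_dseg

DEFAULT_TIERS = ((1, 2), (3, 4), (9,))


@dataclass(frozen=True)
class QueryRow:
    hospital_id: str
    name: str
    trauma_level: int
    capacity: int
    driving_time_s: float | None
    driving_time_min: int | None
    reachable: bool


@dataclass
class MCIQueryResult:
    """Ranked hospital list for one incident location."""

    incident_xy: tuple
    snapped_dseg: str
    reference: str
    rows: list = field(default_factory=list)  # QueryRow, nearest first, unreachable last


@dataclass
class AllocationPlan:
    assignments: list = field(default_factory=list)  # (patient_index, hospital_id, minutes)
    residual_capacities: dict = field(default_factory=dict)
    unassigned: int = 0


def query_mci(
    location,
    reference: str,
    registry: HospitalRegistry,
    table: DrivingTimeTable,
    layer,
) -> MCIQueryResult:
    """Rank all included hospitals by driving time from an incident location.

    The location may be off-network; it snaps to the nearest discretized
    part.  Rows are ordered by driving time (unreachable hospitals last,
    ties by hospital id); excluded hospitals never appear.
    """
    included = registry.included()
    if not included:
        raise ValueError("no hospitals are included in the analysis")
    dseg_id = snap_point_to_dseg(location, layer)
    rows = []
    for h in included:
        seconds = lookup_time(table, dseg_id, h.hospital_id)
        if seconds is UNREACHABLE:
            rows.append(
                QueryRow(h.hospital_id, h.name, h.trauma_level, h.capacity, None, None, False)
            )
        else:
            rows.append(
                QueryRow(
                    h.hospital_id, h.name, h.trauma_level, h.capacity,
                    seconds, lookup_time(table, dseg_id, h.hospital_id, rounding=True), True,
                )
            )
    rows.sort(
        key=lambda r: (not r.reachable, r.driving_time_s if r.reachable else 0.0, r.hospital_id)
    )
    return MCIQueryResult(
        incident_xy=(float(location[0]), float(location[1])),
        snapped_dseg=dseg_id,
        reference=reference,
        rows=rows,
    )


def allocate_patients(
    result: MCIQueryResult,
    n_critical: int,
    registry: HospitalRegistry | None = None,
    tiers=DEFAULT_TIERS,
) -> AllocationPlan:
    """Greedy nearest-with-capacity allocation within trauma-priority tiers.

    Capacities start from the registry's current values (or the query
    snapshot if no registry is given) and are decremented per assignment;
    a hospital never receives more than its starting capacity.
    """
    if n_critical < 0:
        raise ValueError("n_critical must be >= 0")
    residual = {}
    times = {}
    for row in result.rows:
        if not row.reachable:
            continue
        cap = registry[row.hospital_id].capacity if registry is not None else row.capacity
        residual[row.hospital_id] = cap
        times[row.hospital_id] = (row.driving_time_s, row.driving_time_min, row.trauma_level)

    plan = AllocationPlan(residual_capacities=dict(residual))
    for patient in range(n_critical):
        chosen = None
        for tier in tiers:
            candidates = [
                hid
                for hid, cap in residual.items()
                if cap > 0 and times[hid][2] in tier
            ]
            if candidates:
                chosen = min(candidates, key=lambda hid: (times[hid][0], hid))
                break
        if chosen is None:
            plan.unassigned = n_critical - patient
            break
        residual[chosen] -= 1
        plan.assignments.append((patient, chosen, times[chosen][1]))
    plan.residual_capacities = residual
    return plan


# ---------------------------------------------------------------------------
# reporting

_QUERY_COLUMNS = ["hospital_id", "name", "trauma_level", "capacity", "driving_time_min", "reachable"]
_PLAN_COLUMNS = ["patient_index", "hospital_id", "driving_time_min"]


def _query_records(result: MCIQueryResult) -> list:
    return [
        {
            "hospital_id": r.hospital_id,
            "name": r.name,
            "trauma_level": r.trauma_level,
            "capacity": r.capacity,
            "driving_time_min": r.driving_time_min,
            "reachable": r.reachable,
        }
        for r in result.rows
    ]


def _plan_records(plan: AllocationPlan) -> list:
    return [
        {"patient_index": i, "hospital_id": hid, "driving_time_min": minutes}
        for i, hid, minutes in plan.assignments
    ]


def report(obj, format: str = "table") -> str:
    """Serialize a query result or allocation plan as table, json or csv.

    Driving times are shown in whole minutes, the granularity decision
    makers and ambulance logs use.
    """
    if isinstance(obj, MCIQueryResult):
        records, columns = _query_records(obj), _QUERY_COLUMNS
        extra = {
            "incident_xy": list(obj.incident_xy),
            "snapped_dseg": obj.snapped_dseg,
            "reference": obj.reference,
        }
    elif isinstance(obj, AllocationPlan):
        records, columns = _plan_records(obj), _PLAN_COLUMNS
        extra = {
            "residual_capacities": dict(sorted(obj.residual_capacities.items())),
            "unassigned": obj.unassigned,
        }
    else:
        raise TypeError(f"cannot report a {type(obj).__name__}")

    if format == "json":
        return json.dumps({**extra, "rows": records}, indent=1, sort_keys=True)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=columns, lineterminator="\n")
        writer.writeheader()
        writer.writerows(records)
        return buf.getvalue()
    if format == "table":
        widths = {
            c: max(len(c), *(len(str(r[c])) for r in records)) if records else len(c)
            for c in columns
        }
        lines = [
            "  ".join(c.ljust(widths[c]) for c in columns),
            "  ".join("-" * widths[c] for c in columns),
        ]
        for r in records:
            lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in columns))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
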