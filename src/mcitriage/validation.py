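"""Model-vs-ambulance driving-time comparison.

Ambulance services log trip times in whole minutes on paper sheets, so
the comparison works at minute granularity: model times are rounded
(half up) to the minute, deviations are model − ambulance (positive
means the model overestimates), and trips are filtered to the off-peak
windows — 7 pm to 7 am and 12 to 3 pm — where posted speed limits best
approximate achievable speeds.  Repeated trips between one origin and
one destination expose the irreducible variability of real driving
times around the model's single constant.

A small logged dataset of hospital-transfer trips between a suburban
hospital (SMH) and a regional trauma centre (RCH) ships with the
package; see ``bundled_trip_log``.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field
from datetime import time as clock_time
from importlib import resources
from pathlib import Path

from .odmatrix import UNREACHABLE, DrivingTimeTable, lookup_time, snap_point_to_dseg

#: closed at the start, open at the end; the first interval wraps midnight
DEFAULT_TIME_WINDOWS = ((clock_time(19, 0), clock_time(7, 0)), (clock_time(12, 0), clock_time(15, 0)))


@dataclass(frozen=True)
class TripRecord:
    origin: str
    destination: str
    depart_time: clock_time | None
    model_min: int
    ambulance_min: int
    model_min_original: int | None = None  # preserved when model time is recomputed

    def __post_init__(self) -> None:
        if self.model_min < 0 or self.ambulance_min < 0:
            raise ValueError("trip times must be >= 0")


@dataclass
class ODGroup:
    """Repeated trips sharing one exact (origin, destination) pair."""

    origin: str
    destination: str
    count: int
    model_constant: bool  # single model time across the group?
    model_times: tuple
    ambulance_min: int
    ambulance_max: int
    ambulance_spread: int


@dataclass
class ValidationSummary:
    n_trips: int
    deviations: list  # model - ambulance, minutes, per trip
    mean_dev: float
    median_dev: float
    min_ambulance: int
    max_ambulance: int
    per_od_groups: dict = field(default_factory=dict)  # (origin, destination) -> ODGroup

    def to_dict(self) -> dict:
        return {
            "n_trips": self.n_trips,
            "mean_dev_min": self.mean_dev,
            "median_dev_min": self.median_dev,
            "min_ambulance_min": self.min_ambulance,
            "max_ambulance_min": self.max_ambulance,
            "per_od_groups": {
                f"{o}->{d}": {
                    "count": g.count,
                    "model_constant": g.model_constant,
                    "ambulance_min": g.ambulance_min,
                    "ambulance_max": g.ambulance_max,
                    "ambulance_spread": g.ambulance_spread,
                }
                for (o, d), g in sorted(self.per_od_groups.items())
            },
        }


def bundled_trip_log() -> Path:
    """Path to the packaged SMH→RCH ambulance transfer log (11 trips)."""
    return Path(resources.files("mcitriage").joinpath("data", "smh_rch_trips.csv"))


def _parse_clock(text: str):
    text = text.strip()
    if not text:
        return None
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"malformed clock time {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return clock_time(h, m, s)


def load_trip_log(path: str | Path) -> list:
    """Read trips from CSV: origin,destination,depart_time,model_min,ambulance_min.

    ``depart_time`` (HH:MM, 24 h) may be blank; negative or malformed
    times are hard errors naming the row.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return records
        required = {"origin", "destination", "depart_time", "model_min", "ambulance_min"}
        if not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: trip log must have columns {sorted(required)}")
        for rowno, row in enumerate(reader, start=2):
            try:
                records.append(
                    TripRecord(
                        origin=row["origin"].strip(),
                        destination=row["destination"].strip(),
                        depart_time=_parse_clock(row["depart_time"] or ""),
                        model_min=int(row["model_min"]),
                        ambulance_min=int(row["ambulance_min"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} row {rowno}: {exc}") from exc
    return records


def _in_window(t: clock_time, start: clock_time, end: clock_time) -> bool:
    # [start, end); an interval with start >= end wraps past midnight
    if start < end:
        return start <= t < end
    return t >= start or t < end


def filter_by_time_windows(records, windows=DEFAULT_TIME_WINDOWS) -> list:
    """Keep trips departing within any clock window.

    Records without a departure time are kept only when the window list is
    empty (no filtering requested).
    """
    windows = tuple(windows)
    if not windows:
        return list(records)
    return [
        r
        for r in records
        if r.depart_time is not None
        and any(_in_window(r.depart_time, s, e) for s, e in windows)
    ]


def summarize_deviation(records) -> ValidationSummary:
    """Per-trip deviations (model − ambulance) and same-OD variability."""
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty trip log")
    deviations = [r.model_min - r.ambulance_min for r in records]
    groups: dict = {}
    for r in records:
        groups.setdefault((r.origin, r.destination), []).append(r)
    per_od = {}
    for key, trips in groups.items():
        amb = [t.ambulance_min for t in trips]
        model = tuple(sorted({t.model_min for t in trips}))
        per_od[key] = ODGroup(
            origin=key[0],
            destination=key[1],
            count=len(trips),
            model_constant=len(model) == 1,
            model_times=model,
            ambulance_min=min(amb),
            ambulance_max=max(amb),
            ambulance_spread=max(amb) - min(amb),
        )
    return ValidationSummary(
        n_trips=len(records),
        deviations=deviations,
        mean_dev=statistics.fmean(deviations),
        median_dev=statistics.median(deviations),
        min_ambulance=min(r.ambulance_min for r in records),
        max_ambulance=max(r.ambulance_min for r in records),
        per_od_groups=per_od,
    )


def compare_to_model(
    records,
    table: DrivingTimeTable,
    layer,
    origin_points: dict,
    destination_hospitals: dict,
) -> list:
    """Replace each trip's model time with a rounded table lookup.

    ``origin_points`` maps origin labels to (x, y) network points;
    ``destination_hospitals`` maps destination labels to hospital ids in
    the table.  The original model time is preserved alongside.  Labels
    without a mapping are an error listing all of them.
    """
    missing = sorted(
        {r.origin for r in records if r.origin not in origin_points}
        | {r.destination for r in records if r.destination not in destination_hospitals}
    )
    if missing:
        raise ValueError(f"unmapped trip labels: {missing}")
    out = []
    snapped = {label: snap_point_to_dseg(pt, layer) for label, pt in origin_points.items()}
    for r in records:
        minutes = lookup_time(
            table, snapped[r.origin], destination_hospitals[r.destination], rounding=True
        )
        if minutes is UNREACHABLE:
            raise ValueError(f"no route from {r.origin} to {r.destination} in the table")
        out.append(
            TripRecord(
                origin=r.origin,
                destination=r.destination,
                depart_time=r.depart_time,
                model_min=minutes,
                ambulance_min=r.ambulance_min,
                model_min_original=r.model_min,
            )
        )
    return out


def write_paired_times(records, path: str | Path) -> None:
    """Paired model/ambulance minutes as CSV, one row per trip (for plotting)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model_min", "ambulance_min"])
        for r in records:
            writer.writerow([r.model_min, r.ambulance_min])
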