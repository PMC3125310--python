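"""Model configuration.

The travel-time model has three substantive parameters: the maximum
discretized segment length (200 m), and the fixed intersection impedances
for stop signs (5 s) and traffic lights (10 s).  A dimensionless speed
factor lets an ambulance be modelled as faster (or slower) than the posted
limit; the neutral default is 1.0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

DEFAULT_EXCLUDED_CLASSES = frozenset({"back_road", "logging_road"})


@dataclass(frozen=True)
class ModelConfig:
    """Parameters governing discretization and travel-time computation.

    Attributes
    ----------
    max_segment_length_m : float
        Maximum length of a discretized road segment, metres.
    stop_sign_delay_s : float
        Impedance charged when entering a stop-sign-controlled intersection.
    traffic_light_delay_s : float
        Impedance charged when entering a signalised intersection.
    vehicle_speed_factor : float
        Multiplier on posted speed limits (> 1 models a vehicle moving
        faster than posted, e.g. an ambulance running hot).
    excluded_road_classes : frozenset[str]
        Road classes removed before any travel-time computation.
    """

    max_segment_length_m: float = 200.0
    stop_sign_delay_s: float = 5.0
    traffic_light_delay_s: float = 10.0
    vehicle_speed_factor: float = 1.0
    excluded_road_classes: frozenset = field(default_factory=lambda: DEFAULT_EXCLUDED_CLASSES)

    def __post_init__(self) -> None:
        if self.max_segment_length_m <= 0:
            raise ValueError("max_segment_length_m must be positive")
        if self.stop_sign_delay_s < 0 or self.traffic_light_delay_s < 0:
            raise ValueError("intersection delays must be non-negative")
        if self.vehicle_speed_factor <= 0:
            raise ValueError("vehicle_speed_factor must be positive")
        object.__setattr__(self, "excluded_road_classes", frozenset(self.excluded_road_classes))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_road_classes"] = sorted(self.excluded_road_classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "excluded_road_classes" in d:
            d["excluded_road_classes"] = frozenset(d["excluded_road_classes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load from JSON or flat ``key=value`` text."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_dict(json.loads(text))
        d: dict = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "excluded_road_classes":
                d[key] = frozenset(v.strip() for v in val.split(",") if v.strip())
            else:
                d[key] = float(val)
        return cls.from_dict(d)
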