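"""Domain types for the traffic-exposure aggregation pipeline.

Everything lives in a single projected planar coordinate frame measured in
meters; no geodesic math is done anywhere.  Roads are arterial polylines
carrying AADT (average annual daily traffic, vehicles/day) and its heavy
vehicle component; parcels are residential points with a household size;
areal units are the three nested census-style levels the analysis compares
(block group within tract within ZCTA).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Optional

from shapely.geometry import LineString, Point, Polygon


class TrapfairError(Exception):
    """Base class for package errors."""


class ConfigurationError(TrapfairError):
    """Invalid synthetic-county configuration; names the offending field."""


class GeometryError(TrapfairError):
    """Degenerate or invalid geometry supplied to a spatial measure."""


class InputError(TrapfairError):
    """Malformed tabular/vector input (lengths, schema, missing records)."""


class PipelineError(TrapfairError):
    """A pipeline stage failed; carries the stage name for context."""


class RoadClass(str, enum.Enum):
    PRINCIPAL_ARTERIAL = "principal_arterial"
    MINOR_ARTERIAL = "minor_arterial"
    OTHER = "other"


#: Road classes that count as "arterial" for the proximity measures.
ARTERIAL_CLASSES = frozenset({RoadClass.PRINCIPAL_ARTERIAL, RoadClass.MINOR_ARTERIAL})


class Level(str, enum.Enum):
    BLOCK_GROUP = "block_group"
    TRACT = "tract"
    ZCTA = "zcta"


#: Levels ordered fine -> coarse.
LEVELS = (Level.BLOCK_GROUP, Level.TRACT, Level.ZCTA)


@dataclass(frozen=True)
class RoadSegment:
    """An arterial (or other) road polyline with traffic attributes."""

    segment_id: str
    geometry: LineString
    aadt: float
    truck_aadt: float
    road_class: RoadClass

    def __post_init__(self) -> None:
        if len(self.geometry.coords) < 2 or self.geometry.length <= 0:
            raise GeometryError(
                f"road {self.segment_id}: geometry must have >= 2 vertices and length > 0"
            )
        if self.aadt < 0 or self.truck_aadt < 0:
            raise InputError(f"road {self.segment_id}: AADT values must be >= 0")
        if self.truck_aadt > self.aadt * (1 + 1e-12):
            raise InputError(f"road {self.segment_id}: truck_aadt exceeds aadt")


@dataclass(frozen=True)
class Parcel:
    """A tax-assessor parcel point; residential parcels locate households."""

    parcel_id: str
    location: Point
    is_residential: bool
    household_size: int

    def __post_init__(self) -> None:
        if self.household_size < 0 or self.household_size != int(self.household_size):
            raise InputError(
                f"parcel {self.parcel_id}: household_size must be a non-negative integer"
            )


@dataclass(frozen=True)
class ArealUnit:
    """One polygon of a nested areal partition (block group, tract or ZCTA)."""

    unit_id: str
    level: Level
    geometry: Polygon
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise GeometryError(f"unit {self.unit_id}: polygon must have area > 0")


@dataclass(frozen=True)
class DemographicRecord:
    """Per-unit racial composition and material deprivation covariates."""

    unit_id: str
    level: Level
    fraction_nh_black: float
    deprivation_index: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_nh_black <= 1.0:
            raise InputError(
                f"unit {self.unit_id}: fraction_nh_black must lie in [0, 1]"
            )


@dataclass(frozen=True)
class CountyConfig:
    """Parameters of the synthetic county generator.

    Defaults emulate a mixed urban/suburban county of roughly 1,100 km^2
    partitioned into 697 block groups, with arterial roads whose AADT is
    heavy-tailed (log-normal) and residential parcels clustered into
    neighborhoods.  ``demographic_road_correlation`` is the rank correlation
    injected between a unit's road-length density and its demographic
    covariates, the knob that lets fairness findings be seeded and recovered.
    """

    county_width: float = 33_000.0
    county_height: float = 33_000.0
    n_block_groups: int = 697
    tracts_per_side_factor: int = 3
    n_road_segments: int = 2098
    aadt_log_mean: float = 10.8
    aadt_log_sd: float = 1.0
    truck_fraction_mean: float = 0.1
    n_parcels: int = 20_000
    parcel_cluster_count: int = 40
    parcel_cluster_sd: float = 1200.0
    household_size_mean: float = 2.4
    demographic_road_correlation: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        if not self.county_width > 0:
            raise ConfigurationError("county_width must be > 0")
        if not self.county_height > 0:
            raise ConfigurationError("county_height must be > 0")
        for field in ("n_block_groups", "tracts_per_side_factor",
                      "parcel_cluster_count"):
            if getattr(self, field) < 1:
                raise ConfigurationError(f"{field} must be >= 1")
        for field in ("n_road_segments", "n_parcels"):
            if getattr(self, field) < 0:
                raise ConfigurationError(f"{field} must be >= 0")
        if not 0.0 <= self.truck_fraction_mean <= 1.0:
            raise ConfigurationError("truck_fraction_mean must lie in [0, 1]")
        if not -1.0 <= self.demographic_road_correlation <= 1.0:
            raise ConfigurationError(
                "demographic_road_correlation must lie in [-1, 1]"
            )
        if not self.parcel_cluster_sd > 0:
            raise ConfigurationError("parcel_cluster_sd must be > 0")
        if not self.household_size_mean >= 0:
            raise ConfigurationError("household_size_mean must be >= 0")
        for field in ("aadt_log_sd",):
            if getattr(self, field) < 0:
                raise ConfigurationError(f"{field} must be >= 0")
        if not math.isfinite(self.aadt_log_mean):
            raise ConfigurationError("aadt_log_mean must be finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CountyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)
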