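"""Readers and writers for the pipeline's file formats.

Vector layers are GeoJSON FeatureCollections (plain JSON, stdlib round-trip
preserves float64 exactly); tables are CSV.  All geometry is expected in one
projected planar frame in meters — a bounding box that fits inside
longitude/latitude degree ranges is treated as evidence of geographic
coordinates and rejected with instructions to project first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd
from shapely.geometry import mapping, shape

from .types import (
    ArealUnit,
    ConfigurationError,
    CountyConfig,
    DemographicRecord,
    InputError,
    Level,
    Parcel,
    RoadClass,
    RoadSegment,
)

__all__ = [
    "write_roads", "read_roads",
    "write_parcels", "read_parcels",
    "write_units", "read_units",
    "write_demographics", "read_demographics",
    "load_config", "write_config",
    "check_projected",
]

PathLike = Union[str, Path]

DEMOGRAPHICS_COLUMNS = ["unit_id", "level", "fraction_nh_black", "deprivation_index"]


def _feature_collection(features: List[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write_geojson(path: PathLike, features: List[dict]) -> None:
    Path(path).write_text(json.dumps(_feature_collection(features), indent=None))


def _read_features(path: PathLike) -> List[dict]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection" or "features" not in data:
        raise InputError(f"{path}: not a GeoJSON FeatureCollection")
    return data["features"]


def _require(props: dict, key: str, path: PathLike) -> object:
    if key not in props:
        raise InputError(f"{path}: feature missing required attribute {key!r}")
    return props[key]


def check_projected(geoms) -> None:
    """Reject coordinates that look geographic (degrees) rather than metric.

    Heuristic: if the overall bounding box fits within [-180, 180] x [-90, 90]
    the data are almost certainly lon/lat degrees; all measures assume
    projected meters.
    """
    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)
    if -180.0 <= minx <= maxx <= 180.0 and -90.0 <= miny <= maxy <= 90.0:
        raise InputError(
            "coordinates look geographic (lon/lat degrees): bounding box "
            f"({minx:.3f}, {miny:.3f}, {maxx:.3f}, {maxy:.3f}) fits in degree "
            "ranges; project the data to a planar metric CRS first"
        )


# -- roads ----------------------------------------------------------------

def write_roads(roads: Sequence[RoadSegment], path: PathLike) -> None:
    _write_geojson(path, [
        {
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {
                "segment_id": r.segment_id,
                "aadt": r.aadt,
                "truck_aadt": r.truck_aadt,
                "road_class": r.road_class.value,
            },
        }
        for r in roads
    ])


def read_roads(path: PathLike) -> List[RoadSegment]:
    roads = []
    for feat in _read_features(path):
        props = feat.get("properties", {})
        roads.append(
            RoadSegment(
                segment_id=str(_require(props, "segment_id", path)),
                geometry=shape(feat["geometry"]),
                aadt=float(_require(props, "aadt", path)),
                truck_aadt=float(_require(props, "truck_aadt", path)),
                road_class=RoadClass(_require(props, "road_class", path)),
            )
        )
    return roads


# -- parcels --------------------------------------------------------------

def write_parcels(parcels: Sequence[Parcel], path: PathLike) -> None:
    _write_geojson(path, [
        {
            "type": "Feature",
            "geometry": mapping(p.location),
            "properties": {
                "parcel_id": p.parcel_id,
                "is_residential": p.is_residential,
                "household_size": p.household_size,
            },
        }
        for p in parcels
    ])


def read_parcels(path: PathLike) -> List[Parcel]:
    parcels = []
    for feat in _read_features(path):
        props = feat.get("properties", {})
        parcels.append(
            Parcel(
                parcel_id=str(_require(props, "parcel_id", path)),
                location=shape(feat["geometry"]),
                is_residential=bool(_require(props, "is_residential", path)),
                household_size=int(_require(props, "household_size", path)),
            )
        )
    return parcels


# -- areal units ----------------------------------------------------------

def write_units(units: Sequence[ArealUnit], path: PathLike) -> None:
    _write_geojson(path, [
        {
            "type": "Feature",
            "geometry": mapping(u.geometry),
            "properties": {
                "unit_id": u.unit_id,
                "level": u.level.value,
                "parent_id": u.parent_id,
            },
        }
        for u in units
    ])


def read_units(path: PathLike) -> List[ArealUnit]:
    units = []
    for feat in _read_features(path):
        props = feat.get("properties", {})
        parent = props.get("parent_id")
        units.append(
            ArealUnit(
                unit_id=str(_require(props, "unit_id", path)),
                level=Level(_require(props, "level", path)),
                geometry=shape(feat["geometry"]),
                parent_id=None if parent is None else str(parent),
            )
        )
    return units


# -- demographics ---------------------------------------------------------

def write_demographics(records: Sequence[DemographicRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "unit_id": r.unit_id,
            "level": r.level.value,
            # repr round-trips float64 exactly; pandas' formatter may not
            "fraction_nh_black": repr(float(r.fraction_nh_black)),
            "deprivation_index": repr(float(r.deprivation_index)),
        }
        for r in records
    )
    if df.empty:
        df = pd.DataFrame(columns=DEMOGRAPHICS_COLUMNS)
    df.to_csv(path, index=False)


def read_demographics(path: PathLike) -> List[DemographicRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DEMOGRAPHICS_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: demographics CSV missing columns {sorted(missing)}")
    return [
        DemographicRecord(
            unit_id=str(row.unit_id),
            level=Level(row.level),
            fraction_nh_black=float(row.fraction_nh_black),
            deprivation_index=float(row.deprivation_index),
        )
        for row in df.itertuples()
    ]


# -- config ---------------------------------------------------------------

def load_config(path: PathLike) -> CountyConfig:
    """Read a generator config from a YAML or TOML key-value file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml",):
        import tomllib

        data = tomllib.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a key-value mapping")
    return CountyConfig.from_dict(data)


def write_config(config: CountyConfig, path: PathLike) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
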