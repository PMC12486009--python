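"""Seeded synthetic-county generator.

Produces a planar county (projected meters) with the statistical structure the
exposure comparison assumes: arterial road segments with heavy-tailed AADT and
a truck component, residential parcels drawn from Gaussian neighborhood
clusters, three exactly-nested areal partitions (block group < tract < ZCTA),
and per-unit demographic covariates whose rank correlation with unit
road-length density is controllable.  That last knob is what lets fairness
effects be injected and then recovered by the downstream audit.

Nesting is built by recursive rectangular partition: ZCTAs are vertical strips
of the county, each strip is sliced horizontally into its tracts, and each
tract vertically into its block groups.  Real census geography only
approximately nests (ZCTAs are not built from tracts); exact nesting is a
harmless simplification here because each level is analysed independently, and
it makes every unit's parent well defined.
"""

from __future__ import annotations

import math
from typing import List, NamedTuple, Sequence

import numpy as np
from scipy import stats
from shapely import STRtree
from shapely.geometry import LineString, Point, Polygon, box

from .types import (
    ArealUnit,
    ConfigurationError,
    CountyConfig,
    DemographicRecord,
    Level,
    Parcel,
    RoadClass,
    RoadSegment,
)

__all__ = [
    "SyntheticCounty",
    "generate_county",
    "unit_road_density",
    "inject_decile_distortion",
]


class SyntheticCounty(NamedTuple):
    roads: List[RoadSegment]
    parcels: List[Parcel]
    units: List[ArealUnit]
    demographics: List[DemographicRecord]


def _balanced_counts(total: int, parts: int) -> List[int]:
    """Split ``total`` children across ``parts`` parents as evenly as possible."""
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _build_units(config: CountyConfig) -> List[ArealUnit]:
    w, h = config.county_width, config.county_height
    f = config.tracts_per_side_factor
    n_bg = config.n_block_groups
    n_tr = math.ceil(n_bg / f)
    n_z = math.ceil(n_tr / f)

    units: List[ArealUnit] = []
    # ZCTAs: vertical strips.
    zx = np.linspace(0.0, w, n_z + 1)
    zcta_ids = [f"Z{i:03d}" for i in range(n_z)]
    for i, zid in enumerate(zcta_ids):
        units.append(ArealUnit(zid, Level.ZCTA, box(zx[i], 0.0, zx[i + 1], h), None))

    # Tracts: each strip sliced horizontally.
    tracts_per_z = _balanced_counts(n_tr, n_z)
    tract_ids: List[str] = []
    tract_boxes: List[Polygon] = []
    t = 0
    for i, k in enumerate(tracts_per_z):
        ty = np.linspace(0.0, h, k + 1)
        for j in range(k):
            tid = f"T{t:04d}"
            geom = box(zx[i], ty[j], zx[i + 1], ty[j + 1])
            units.append(ArealUnit(tid, Level.TRACT, geom, zcta_ids[i]))
            tract_ids.append(tid)
            tract_boxes.append(geom)
            t += 1

    # Block groups: each tract sliced vertically.
    bgs_per_tract = _balanced_counts(n_bg, n_tr)
    b = 0
    for tid, tgeom, k in zip(tract_ids, tract_boxes, bgs_per_tract):
        minx, miny, maxx, maxy = tgeom.bounds
        bx = np.linspace(minx, maxx, k + 1)
        for j in range(k):
            units.append(
                ArealUnit(
                    f"B{b:05d}",
                    Level.BLOCK_GROUP,
                    box(bx[j], miny, bx[j + 1], maxy),
                    tid,
                )
            )
            b += 1
    return units


def _clip_to_county(geom: LineString, county: Polygon) -> LineString | None:
    clipped = geom.intersection(county)
    if clipped.is_empty:
        return None
    if clipped.geom_type == "LineString":
        return clipped if clipped.length > 0 else None
    if clipped.geom_type == "MultiLineString":
        # keep the longest piece; chords of a rectangle rarely split
        parts = [g for g in clipped.geoms if g.length > 0]
        return max(parts, key=lambda g: g.length) if parts else None
    return None


def _build_roads(config: CountyConfig, rng: np.random.Generator) -> List[RoadSegment]:
    n = config.n_road_segments
    if n == 0:
        return []
    w, h = config.county_width, config.county_height
    county = box(0.0, 0.0, w, h)
    n_highway = int(round(0.1 * n)) if n >= 10 else 0

    roads: List[RoadSegment] = []
    aadt = rng.lognormal(config.aadt_log_mean, config.aadt_log_sd, size=n)
    truck_frac = np.clip(
        rng.normal(config.truck_fraction_mean,
                   max(config.truck_fraction_mean / 3.0, 1e-6), size=n),
        0.0, 1.0,
    )

    for i in range(n):
        if i < n_highway:
            # long chord crossing the county, alternating orientation
            if i % 2 == 0:
                p0 = (0.0, rng.uniform(0.0, h))
                p1 = (w, rng.uniform(0.0, h))
            else:
                p0 = (rng.uniform(0.0, w), 0.0)
                p1 = (rng.uniform(0.0, w), h)
            geom = LineString([p0, p1])
            cls = RoadClass.PRINCIPAL_ARTERIAL
        else:
            # local segment: random center, direction and heavy-tailed length
            cx, cy = rng.uniform(0.0, w), rng.uniform(0.0, h)
            theta = rng.uniform(0.0, math.pi)
            half = 0.5 * rng.lognormal(math.log(800.0), 0.6)
            dx, dy = half * math.cos(theta), half * math.sin(theta)
            geom = _clip_to_county(
                LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)]), county
            )
            if geom is None:
                # degenerate clip: fall back to a short in-county stub
                geom = LineString([(cx, cy), (min(cx + 10.0, w), cy)])
            cls = (RoadClass.MINOR_ARTERIAL if rng.random() < 0.75
                   else RoadClass.OTHER)
        roads.append(
            RoadSegment(
                segment_id=f"R{i:05d}",
                geometry=geom,
                aadt=float(aadt[i]),
                truck_aadt=float(aadt[i] * truck_frac[i]),
                road_class=cls,
            )
        )
    return roads


def _build_parcels(config: CountyConfig, rng: np.random.Generator) -> List[Parcel]:
    n = config.n_parcels
    if n == 0:
        return []
    w, h = config.county_width, config.county_height
    centers = rng.uniform([0.0, 0.0], [w, h], size=(config.parcel_cluster_count, 2))
    assignment = rng.integers(0, config.parcel_cluster_count, size=n)
    xy = centers[assignment] + rng.normal(0.0, config.parcel_cluster_sd, size=(n, 2))
    # truncate the Gaussian clusters to the county by resampling strays
    out = (xy[:, 0] < 0) | (xy[:, 0] > w) | (xy[:, 1] < 0) | (xy[:, 1] > h)
    while out.any():
        idx = np.flatnonzero(out)
        xy[idx] = centers[assignment[idx]] + rng.normal(
            0.0, config.parcel_cluster_sd, size=(len(idx), 2)
        )
        out = (xy[:, 0] < 0) | (xy[:, 0] > w) | (xy[:, 1] < 0) | (xy[:, 1] > h)
    household = rng.poisson(config.household_size_mean, size=n)
    residential = rng.random(n) < 0.9
    return [
        Parcel(
            parcel_id=f"P{i:06d}",
            location=Point(float(xy[i, 0]), float(xy[i, 1])),
            is_residential=bool(residential[i]),
            household_size=int(household[i]),
        )
        for i in range(n)
    ]


def unit_road_density(roads: Sequence[RoadSegment],
                      units: Sequence[ArealUnit]) -> np.ndarray:
    """Road length per unit area (m/m^2) for each unit, clipped to the unit."""
    if not roads:
        return np.zeros(len(units))
    geoms = [r.geometry for r in roads]
    tree = STRtree(geoms)
    out = np.zeros(len(units))
    for i, u in enumerate(units):
        cand = sorted(tree.query(u.geometry, predicate="intersects"))
        total = 0.0
        for j in cand:
            total += geoms[j].intersection(u.geometry).length
        out[i] = total / u.geometry.area
    return out


def _copula_covariates(density: np.ndarray, r: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (fraction_nh_black, deprivation_index) with Spearman ~ r vs density.

    Gaussian copula: the density ranks are mapped to normal scores; each
    covariate's latent normal is correlated rho = 2 sin(pi r / 6) with those
    scores (the classical Pearson<->Spearman relation for bivariate normals),
    then pushed through a marginal transform.  Monotone marginals preserve the
    rank correlation.
    """
    n = len(density)
    ranks = stats.rankdata(density, method="average")
    scores = stats.norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom normal scores
    sd = scores.std()
    scores = scores / sd if sd > 0 else np.zeros(n)
    rho = float(np.clip(2.0 * math.sin(math.pi * r / 6.0), -1.0, 1.0))

    def latent() -> np.ndarray:
        return rho * scores + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)

    u_black = stats.norm.cdf(latent())
    u_dep = stats.norm.cdf(latent())
    # fraction non-Hispanic Black: right-skewed Beta marginal (county-like)
    frac_black = stats.beta.ppf(u_black, 1.5, 5.0)
    # deprivation index: a 0-1 composite score, uniform marginal
    dep = u_dep
    return np.clip(frac_black, 0.0, 1.0), dep


def _build_demographics(config: CountyConfig, units: Sequence[ArealUnit],
                        roads: Sequence[RoadSegment],
                        rng: np.random.Generator) -> List[DemographicRecord]:
    records: List[DemographicRecord] = []
    for level in Level:
        level_units = [u for u in units if u.level == level]
        density = unit_road_density(roads, level_units)
        frac_black, dep = _copula_covariates(
            density, config.demographic_road_correlation, rng
        )
        for u, fb, d in zip(level_units, frac_black, dep):
            records.append(DemographicRecord(u.unit_id, level, float(fb), float(d)))
    return records


def generate_county(config: CountyConfig) -> SyntheticCounty:
    """Generate a complete synthetic county; identical seeds give identical output.

    Returns roads, parcels, areal units at all three levels, and one
    demographic record per unit per level.

    Raises :class:`~trapfair.types.ConfigurationError` for invalid configs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    units = _build_units(config)
    roads = _build_roads(config, rng)
    parcels = _build_parcels(config, rng)
    demographics = _build_demographics(config, units, roads, rng)
    return SyntheticCounty(roads, parcels, units, demographics)


def inject_decile_distortion(reference_deciles: np.ndarray,
                             covariate: np.ndarray,
                             slope: float,
                             noise_sd: float = 0.75,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Distort reference deciles so the expected decile error tracks a covariate.

    Emulates an aggregation artifact (e.g. a centroid-based measure inflated in
    units with high covariate values): each unit's candidate decile is the
    reference decile plus an integer shift whose expectation is
    ``slope * z(covariate)`` (z = standardized covariate) plus mean-zero noise.
    Integerization uses stochastic rounding, so E[error] equals the target
    exactly before clipping to the 1..10 decile range.  Used to validate that
    the fairness regression recovers injected effects.
    """
    rng = np.random.default_rng() if rng is None else rng
    ref = np.asarray(reference_deciles, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if cov.std(ddof=1) == 0:
        raise ConfigurationError("covariate must have nonzero variance")
    z = (cov - cov.mean()) / cov.std(ddof=1)
    shift = slope * z + rng.normal(0.0, noise_sd, size=len(ref))
    base = np.floor(shift)
    shift_int = base + (rng.random(len(ref)) < (shift - base))
    return np.clip(ref + shift_int, 1, 10).astype(int)
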