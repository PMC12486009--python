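import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from trapfair.types import (
    ArealUnit,
    CountyConfig,
    Level,
    Parcel,
    RoadClass,
    RoadSegment,
)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured county: 3 levels, clusters, highways."""
    return CountyConfig(
        county_width=9000.0,
        county_height=9000.0,
        n_block_groups=45,
        tracts_per_side_factor=3,
        n_road_segments=150,
        n_parcels=1500,
        parcel_cluster_count=8,
        parcel_cluster_sd=600.0,
        demographic_road_correlation=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_county(small_config):
    from trapfair.synthetic import generate_county

    return generate_county(small_config)


@pytest.fixture
def square_unit():
    """1 km x 1 km block group centered at the origin (centroid (0, 0))."""
    return ArealUnit("U1", Level.BLOCK_GROUP, box(-500, -500, 500, 500))


def make_road(segment_id, coords, aadt, truck_aadt=None,
              road_class=RoadClass.MINOR_ARTERIAL):
    return RoadSegment(
        segment_id=segment_id,
        geometry=LineString(coords),
        aadt=aadt,
        truck_aadt=aadt * 0.1 if truck_aadt is None else truck_aadt,
        road_class=road_class,
    )


def make_parcel(parcel_id, x, y, household_size=2, is_residential=True):
    return Parcel(parcel_id, Point(x, y), is_residential, household_size)


def random_geometry_case(rng):
    """One random small test geometry: a rectangular unit, <= 10 road
    segments (1- or 2-piece polylines) around it, and a handful of parcels."""
    w = rng.uniform(400, 1500)
    h = rng.uniform(400, 1500)
    x0 = rng.uniform(-1000, 1000)
    y0 = rng.uniform(-1000, 1000)
    unit = ArealUnit("G", Level.TRACT, box(x0, y0, x0 + w, y0 + h))
    n_roads = rng.integers(1, 11)
    roads = []
    for i in range(n_roads):
        cx = rng.uniform(x0 - 800, x0 + w + 800)
        cy = rng.uniform(y0 - 800, y0 + h + 800)
        theta = rng.uniform(0, np.pi)
        half = rng.uniform(50, 900)
        p0 = (cx - half * np.cos(theta), cy - half * np.sin(theta))
        p1 = (cx + half * np.cos(theta), cy + half * np.sin(theta))
        coords = [p0, p1]
        if rng.random() < 0.3:  # add a vertex so some polylines bend
            mid = ((p0[0] + p1[0]) / 2 + rng.uniform(-100, 100),
                   (p0[1] + p1[1]) / 2 + rng.uniform(-100, 100))
            coords = [p0, mid, p1]
        aadt = float(rng.lognormal(9.5, 0.8))
        classes = [RoadClass.PRINCIPAL_ARTERIAL, RoadClass.MINOR_ARTERIAL,
                   RoadClass.OTHER]
        cls = classes[rng.choice(3, p=[0.3, 0.5, 0.2])]
        roads.append(make_road(f"r{i}", coords, aadt, aadt * 0.12, cls))
    parcels = [
        make_parcel(
            f"p{i}",
            rng.uniform(x0, x0 + w),
            rng.uniform(y0, y0 + h),
            household_size=int(rng.integers(0, 6)),
            is_residential=bool(rng.random() < 0.85),
        )
        for i in range(int(rng.integers(3, 12)))
    ]
    return roads, parcels, unit
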