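"""Tests of the three exposure measures against hand-built geometries,
brute-force oracles and algebraic invariants."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import LineString, box

from trapfair.measures import (
    ExposureEngine,
    MeasureParams,
    aadt_density,
    compute_exposure_table,
    ej_screen_proximity,
    parcel_traffic_proximity,
    weighted_median,
)
from trapfair.types import ArealUnit, GeometryError, InputError, Level, RoadClass

from _oracles import (
    brute_aadt_density,
    brute_ej_screen,
    brute_parcel_proximity,
    expanded_weighted_median,
)
from conftest import make_parcel, make_road, random_geometry_case

PARAMS = MeasureParams()


# ---------------------------------------------------------------- EJ Screen

def test_ej_screen_segment_outside_radius_is_zero(square_unit):
    roads = [make_road("r", [(600, -10), (600, 10)], 10_000)]
    assert ej_screen_proximity(roads, square_unit) == 0.0


def test_ej_screen_single_segment_inverse_distance(square_unit):
    # nearest point of the vertical segment x=100 is exactly 100 m from (0,0)
    roads = [make_road("r", [(100, -50), (100, 50)], 10_000)]
    assert ej_screen_proximity(roads, square_unit) == pytest.approx(100.0)


def test_ej_screen_sums_over_segments(square_unit):
    roads = [
        make_road("a", [(100, -50), (100, 50)], 10_000),
        make_road("b", [(-250, -50), (-250, 50)], 5_000),
    ]
    assert ej_screen_proximity(roads, square_unit) == pytest.approx(120.0)


def test_ej_screen_distance_floor_bounds_weight(square_unit):
    # segment through the centroid: d = 0 is floored at 1 m
    roads = [make_road("r", [(-10, 0), (10, 0)], 7_000)]
    assert ej_screen_proximity(roads, square_unit) == pytest.approx(7_000.0)


def test_ej_screen_ignores_non_arterial_roads(square_unit):
    roads = [make_road("r", [(100, -50), (100, 50)], 10_000,
                       road_class=RoadClass.OTHER)]
    assert ej_screen_proximity(roads, square_unit) == 0.0


def test_ej_screen_boundary_segment_at_exact_radius(square_unit):
    roads = [make_road("r", [(500, -50), (500, 50)], 1_000)]
    assert ej_screen_proximity(roads, square_unit) == pytest.approx(2.0)


# ------------------------------------------------------------- AADT density

def test_density_interior_segment(square_unit):
    roads = [make_road("r", [(0, 0), (100, 0)], 1_000)]
    assert aadt_density(roads, square_unit) == pytest.approx(0.1)


def test_density_no_intersection_is_zero(square_unit):
    roads = [make_road("r", [(600, 0), (700, 0)], 1_000)]
    assert aadt_density(roads, square_unit) == 0.0


def test_density_uses_only_clipped_length(square_unit):
    # 400 m segment, 200 m inside the unit
    roads = [make_road("r", [(300, 0), (700, 0)], 1_000)]
    expected = 1_000 * 200 / 1_000_000
    assert aadt_density(roads, square_unit) == pytest.approx(expected)


def test_density_boundary_crossing_matches_point_sampling(square_unit):
    # clipped length approximated by dense sampling along the segment
    roads = [make_road("r", [(-900, -130), (820, 410)], 2_500)]
    sampled = brute_aadt_density(roads, square_unit, n=200_000)
    assert aadt_density(roads, square_unit) == pytest.approx(sampled, rel=1e-3)


def test_density_counts_all_road_classes(square_unit):
    roads = [make_road("r", [(0, 0), (100, 0)], 1_000, road_class=RoadClass.OTHER)]
    assert aadt_density(roads, square_unit) == pytest.approx(0.1)


def test_degenerate_unit_polygon_is_rejected():
    with pytest.raises(GeometryError):
        ArealUnit("bad", Level.TRACT, box(0, 0, 0, 0))


# --------------------------------------------------------- weighted median

@pytest.mark.parametrize(
    "values,weights,expected",
    [
        ([100, 200, 300], [1, 1, 1], 200.0),
        ([100, 300], [3, 1], 100.0),
        ([0, 0, 0], [2, 1, 4], 0.0),
        ([5.0], [3], 5.0),
        ([1, 2, 3, 4], [1, 1, 1, 1], 2.0),  # lower median on even counts
    ],
)
def test_weighted_median_examples(values, weights, expected):
    assert weighted_median(values, weights) == expected


def test_weighted_median_matches_expansion_oracle():
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = rng.integers(1, 30)
        values = rng.integers(0, 1000, n).astype(float)
        weights = rng.integers(0, 5, n)
        assert weighted_median(values, weights) == expanded_weighted_median(
            values, weights
        )


# --------------------------------------------------- parcel traffic proximity

def test_parcel_proximity_all_scores_zero(square_unit):
    parcels = [make_parcel(f"p{i}", x, 0) for i, x in enumerate((-100, 0, 100))]
    roads = [make_road("r", [(0, 2000), (100, 2000)], 10_000)]  # > 400 m away
    assert parcel_traffic_proximity(roads, parcels, square_unit) == 0.0


def test_parcel_proximity_unweighted_median(square_unit):
    # three parcels at increasing distance bands from three separate roads
    parcels = [make_parcel("a", -400, 0, 2), make_parcel("b", 0, 0, 2),
               make_parcel("c", 400, 0, 2)]
    roads = [
        make_road("ra", [(-400, 100), (-390, 100)], 1_000, truck_aadt=100),
        make_road("rb", [(0, 100), (10, 100)], 2_000, truck_aadt=200),
        make_road("rc", [(400, 100), (410, 100)], 3_000, truck_aadt=300),
    ]
    params = MeasureParams(parcel_weighting="unweighted", parcel_radius=150.0)
    assert parcel_traffic_proximity(roads, parcels, square_unit, params) == 200.0


def test_parcel_proximity_household_weighted(square_unit):
    parcels = [make_parcel("a", -400, 0, 3), make_parcel("b", 400, 0, 1)]
    roads = [
        make_road("ra", [(-400, 100), (-390, 100)], 1_000, truck_aadt=100),
        make_road("rb", [(400, 100), (410, 100)], 3_000, truck_aadt=300),
    ]
    params = MeasureParams(parcel_radius=150.0)
    assert parcel_traffic_proximity(roads, parcels, square_unit, params) == 100.0


def test_parcel_proximity_no_parcels_is_zero_not_error(square_unit):
    roads = [make_road("r", [(0, 100), (10, 100)], 1_000)]
    assert parcel_traffic_proximity(roads, [], square_unit) == 0.0


def test_parcel_proximity_ignores_nonresidential_and_outside(square_unit):
    roads = [make_road("r", [(0, 100), (10, 100)], 1_000, truck_aadt=100)]
    parcels = [
        make_parcel("in", 0, 0, 2),
        make_parcel("shop", 10, 0, 2, is_residential=False),
        make_parcel("out", 5_000, 0, 2),
    ]
    assert parcel_traffic_proximity(roads, parcels, square_unit) == 100.0


def test_fraction_near_variant(square_unit):
    roads = [make_road("r", [(0, 100), (10, 100)], 1_000, truck_aadt=100)]
    parcels = [make_parcel("a", 0, 0, 1), make_parcel("b", 450, -450, 1)]
    params = MeasureParams(parcel_statistic="fraction_near",
                           parcel_weighting="unweighted")
    assert parcel_traffic_proximity(roads, parcels, square_unit, params) == 0.5


# -------------------------------------------------------- oracle equivalence

def test_measures_match_bruteforce_on_random_geometries():
    """Implementation vs independent brute force on 25 random small cases."""
    rng = np.random.default_rng(101)
    for _ in range(25):
        roads, parcels, unit, = random_geometry_case(rng)
        ej = ej_screen_proximity(roads, unit, PARAMS)
        assert ej == pytest.approx(brute_ej_screen(roads, unit, PARAMS), rel=1e-9)
        dens = aadt_density(roads, unit)
        assert dens == pytest.approx(brute_aadt_density(roads, unit), rel=1e-9)
        prox = parcel_traffic_proximity(roads, parcels, unit, PARAMS)
        assert prox == pytest.approx(
            brute_parcel_proximity(roads, parcels, unit, PARAMS), rel=1e-9
        )


# ------------------------------------------------------------- invariants

def _scale_roads(roads, c):
    return [
        make_road(r.segment_id, list(r.geometry.coords), r.aadt * c,
                  r.truck_aadt * c, r.road_class)
        for r in roads
    ]


def test_scale_equivariance():
    rng = np.random.default_rng(7)
    roads, parcels, unit = random_geometry_case(rng)
    c = 3.7
    scaled = _scale_roads(roads, c)
    assert aadt_density(scaled, unit) == pytest.approx(
        c * aadt_density(roads, unit), rel=1e-12)
    assert ej_screen_proximity(scaled, unit) == pytest.approx(
        c * ej_screen_proximity(roads, unit), rel=1e-12)
    assert parcel_traffic_proximity(scaled, parcels, unit) == pytest.approx(
        c * parcel_traffic_proximity(roads, parcels, unit), rel=1e-12)


def test_translation_invariance():
    rng = np.random.default_rng(8)
    roads, parcels, unit = random_geometry_case(rng)
    dx, dy = 13_500.0, -8_200.0

    def shift_geom(g):
        return affinity.translate(g, dx, dy)

    roads2 = [make_road(r.segment_id, list(shift_geom(r.geometry).coords),
                        r.aadt, r.truck_aadt, r.road_class) for r in roads]
    parcels2 = [make_parcel(p.parcel_id, p.location.x + dx, p.location.y + dy,
                            p.household_size, p.is_residential) for p in parcels]
    unit2 = ArealUnit(unit.unit_id, unit.level, shift_geom(unit.geometry))
    assert ej_screen_proximity(roads2, unit2) == pytest.approx(
        ej_screen_proximity(roads, unit), rel=1e-9)
    assert aadt_density(roads2, unit2) == pytest.approx(
        aadt_density(roads, unit), rel=1e-9)
    assert parcel_traffic_proximity(roads2, parcels2, unit2) == pytest.approx(
        parcel_traffic_proximity(roads, parcels, unit), rel=1e-9)


def test_adding_nearby_arterial_never_decreases_exposure(square_unit):
    rng = np.random.default_rng(9)
    roads, _, _ = random_geometry_case(rng)
    extra = make_road("extra", [(50, 50), (200, 120)], 4_000)
    for fn in (lambda rs: ej_screen_proximity(rs, square_unit),
               lambda rs: aadt_density(rs, square_unit)):
        assert fn(roads + [extra]) >= fn(roads)


def test_clipping_conserves_length_across_units(small_county):
    """A segment's clipped lengths over one level's tiling sum to its
    in-county length."""
    bgs = [u for u in small_county.units if u.level == Level.BLOCK_GROUP]
    for road in small_county.roads[:20]:
        total = sum(road.geometry.intersection(u.geometry).length for u in bgs)
        assert total == pytest.approx(road.geometry.length, rel=1e-6)


# ------------------------------------------------------------ exposure table

def test_table_matches_per_unit_calls(small_county):
    roads, parcels, units, _ = small_county
    tracts = [u for u in units if u.level == Level.TRACT]
    table = compute_exposure_table(roads, parcels, tracts).set_index("unit_id")
    for u in tracts:
        assert table.loc[u.unit_id, "ej_screen"] == ej_screen_proximity(
            roads, u, PARAMS)
        assert table.loc[u.unit_id, "aadt_density"] == aadt_density(roads, u)
        assert table.loc[u.unit_id, "parcel_proximity"] == parcel_traffic_proximity(
            roads, parcels, u, PARAMS)


def test_table_order_invariance(small_county):
    roads, parcels, units, _ = small_county
    tracts = [u for u in units if u.level == Level.TRACT]
    t1 = compute_exposure_table(roads, parcels, tracts)
    t2 = compute_exposure_table(roads, parcels, tracts[::-1])
    assert t1.equals(t2)


def test_table_rejects_mixed_levels(small_county):
    with pytest.raises(InputError, match="mix"):
        compute_exposure_table(small_county.roads, small_county.parcels,
                               small_county.units)


def test_table_no_roads_all_zero(small_county):
    tracts = [u for u in small_county.units if u.level == Level.TRACT]
    table = compute_exposure_table([], small_county.parcels, tracts)
    assert (table[["ej_screen", "aadt_density", "parcel_proximity"]] == 0).all().all()
    assert (table["n_parcels_used"] <= len(small_county.parcels)).all()
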