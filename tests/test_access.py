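"""Accessibility: snapping, shortest paths, raster proximity, assembly."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

import oracles
from conftest import random_geometric_network
from hlindex import (
    DOMAIN_ORDER,
    POINT_DOMAINS,
    DistanceGrid,
    EnvironmentRaster,
    InputError,
    Meshblock,
    RoadNetwork,
    build_access_table,
    distance_transform,
    euclidean_nearest_distance,
    median_proximity,
    network_nearest_distance,
    rasterize_features,
    snap_to_network,
)


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

def test_snap_point_on_node_has_zero_access(line_network):
    loc = snap_to_network((1000.0, 0.0), line_network)
    assert loc.access_offset == pytest.approx(0.0, abs=1e-9)
    assert loc.offset in (pytest.approx(0.0), pytest.approx(1000.0))


def test_snap_perpendicular_from_edge_midpoint(line_network):
    loc = snap_to_network((500.0, 30.0), line_network)
    assert loc.edge == ("A", "B")
    assert loc.offset == pytest.approx(500.0)
    assert loc.access_offset == pytest.approx(30.0)


def test_snap_empty_network_raises():
    with pytest.raises(InputError):
        snap_to_network((0, 0), RoadNetwork(nodes={}, edges=[]))


def test_snap_matches_exhaustive_segment_scan():
    net = random_geometric_network(50, seed=2)
    rng = np.random.default_rng(0)
    for point in rng.uniform(0, 5000, size=(100, 2)):
        got = snap_to_network(tuple(point), net)
        edge, offset, access = oracles.brute_snap(tuple(point), net)
        assert got.access_offset == pytest.approx(access, abs=1e-6)
        # distance agreement is the contract; the edge may differ only when
        # the snap point is shared (e.g. a common node)
        if abs(got.offset - offset) > 1e-6:
            assert got.access_offset == pytest.approx(access, abs=1e-6)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_euclidean_three_four_five():
    assert euclidean_nearest_distance((0, 0), [(3000.0, 4000.0)]) \
        == pytest.approx(5.0)
    assert euclidean_nearest_distance((7, 7), [(7.0, 7.0)]) == 0.0
    with pytest.raises(InputError):
        euclidean_nearest_distance((0, 0), [])


def test_euclidean_matches_naive_scan():
    rng = np.random.default_rng(4)
    origin = (123.0, 456.0)
    facilities = rng.uniform(0, 10000, size=(1000, 2))
    naive = min(math.hypot(x - origin[0], y - origin[1])
                for x, y in facilities) / 1000.0
    assert euclidean_nearest_distance(origin, facilities) \
        == pytest.approx(naive, abs=1e-12)


def test_network_distance_identity_and_path_sum(line_network):
    assert network_nearest_distance((0.0, 0.0), [(0.0, 0.0)], line_network) \
        == pytest.approx(0.0, abs=1e-9)
    assert network_nearest_distance((0.0, 0.0), [(2000.0, 0.0)],
                                    line_network) == pytest.approx(2.0)
    with pytest.raises(InputError):
        network_nearest_distance((0, 0), [], line_network)


def test_network_distance_matches_brute_force_dijkstra():
    rng = np.random.default_rng(7)
    net = random_geometric_network(80, seed=13)
    for _ in range(20):
        origin = tuple(rng.uniform(0, 5000, size=2))
        facilities = [tuple(p) for p in rng.uniform(0, 5000, size=(3, 2))]
        got = network_nearest_distance(origin, facilities, net)
        want = oracles.brute_network_nearest(origin, facilities, net)
        assert got == pytest.approx(want, abs=1e-6)


def test_network_distance_bounded_below_by_euclidean():
    rng = np.random.default_rng(8)
    net = random_geometric_network(60, seed=21)
    for _ in range(25):
        origin = tuple(rng.uniform(0, 5000, size=2))
        fac = [tuple(rng.uniform(0, 5000, size=2))]
        assert network_nearest_distance(origin, fac, net) \
            >= euclidean_nearest_distance(origin, fac) - 1e-6


def test_adding_a_facility_never_increases_distance():
    rng = np.random.default_rng(9)
    net = random_geometric_network(40, seed=5)
    origin = (2500.0, 2500.0)
    facilities = [tuple(p) for p in rng.uniform(0, 5000, size=(4, 2))]
    base = network_nearest_distance(origin, facilities[:3], net)
    assert network_nearest_distance(origin, facilities, net) <= base + 1e-9


def test_unreachable_facilities_fall_back_to_euclidean(caplog):
    net = RoadNetwork(
        nodes={"A": (0.0, 0.0), "B": (1000.0, 0.0),
               "X": (9000.0, 0.0), "Y": (10000.0, 0.0)},
        edges=[("A", "B", 1000.0), ("X", "Y", 1000.0)])
    with caplog.at_level("WARNING"):
        d = network_nearest_distance((0.0, 0.0), [(9000.0, 0.0)], net)
    assert d == pytest.approx(9.0)
    assert any("fallback" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def test_rasterize_center_in_polygon_rule():
    window = (0.0, 0.0, 200.0, 200.0)
    full = rasterize_features([box(-10, -10, 210, 210)], window)
    assert full.presence.all()
    aligned = rasterize_features([box(0, 0, 100, 100)], window)
    assert aligned.presence.sum() == 4  # 2x2 cells of 50 m
    # a sliver strictly between two columns of cell centres burns nothing
    sliver = rasterize_features([box(30.0, 0.0, 45.0, 200.0)], window)
    assert not sliver.presence.any()
    with pytest.raises(InputError):
        distance_transform(sliver)
    with pytest.raises(InputError):
        rasterize_features([box(0, 0, 1, 1)], (0.0, 0.0, 0.0, 100.0))


def test_distance_transform_steps():
    presence = np.zeros((5, 5), dtype=bool)
    presence[2, 2] = True
    grid = distance_transform(EnvironmentRaster(
        domain="green", origin=(0.0, 0.0), resolution=50.0,
        presence=presence))
    assert grid.values[2, 2] == 0.0
    assert grid.values[2, 3] == pytest.approx(50.0)
    assert grid.values[3, 3] == pytest.approx(50.0 * math.sqrt(2))


def test_distance_transform_matches_exhaustive_oracle():
    rng = np.random.default_rng(3)
    presence = rng.uniform(size=(12, 15)) < 0.15
    presence[4, 7] = True
    raster = EnvironmentRaster(domain="blue", origin=(0.0, 0.0),
                               resolution=50.0, presence=presence)
    got = distance_transform(raster).values
    want = oracles.naive_distance_transform(presence, 50.0)
    assert np.allclose(got, want)


def test_distance_transform_reflection_symmetry():
    rng = np.random.default_rng(6)
    presence = rng.uniform(size=(9, 13)) < 0.2
    presence[0, 0] = True
    base = EnvironmentRaster(domain="green", origin=(0.0, 0.0),
                             resolution=50.0, presence=presence)
    flipped = EnvironmentRaster(domain="green", origin=(0.0, 0.0),
                                resolution=50.0,
                                presence=presence[:, ::-1].copy())
    assert np.allclose(distance_transform(base).values[:, ::-1],
                       distance_transform(flipped).values)


def _meshblock(poly, centroid, mid="mb0"):
    return Meshblock(id=mid, polygon=poly, population=100,
                     centroid=centroid, dep_decile=5,
                     urban_rural="major_urban")


def test_median_proximity_median_and_fallback():
    values = np.array([[0.0, 50.0, 100.0]])
    grid = DistanceGrid(domain="green", origin=(0.0, 0.0), resolution=50.0,
                        values=values)
    mb = _meshblock(box(0, 0, 150, 50), (75.0, 25.0))
    assert median_proximity(mb, grid) == pytest.approx(0.05)
    # fully covered meshblock sits at distance zero
    zero = DistanceGrid(domain="green", origin=(0.0, 0.0), resolution=50.0,
                        values=np.zeros((2, 2)))
    assert median_proximity(_meshblock(box(0, 0, 100, 100), (50.0, 50.0)),
                            zero) == 0.0
    # too small to contain a cell centre: value of the centroid's cell
    tiny_grid = DistanceGrid(domain="blue", origin=(0.0, 0.0),
                             resolution=50.0,
                             values=np.array([[200.0, 400.0]]))
    tiny = _meshblock(Polygon([(1, 1), (6, 1), (6, 6), (1, 6)]), (3.0, 3.0))
    assert median_proximity(tiny, tiny_grid) == pytest.approx(0.2)
    outside = _meshblock(box(500, 500, 510, 510), (505.0, 505.0))
    with pytest.raises(InputError):
        median_proximity(outside, tiny_grid)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_access_table_shape_and_validity(small_region):
    table = build_access_table(small_region)
    assert list(table.distances.columns) == list(DOMAIN_ORDER)
    assert len(table.distances) == 60
    vals = table.distances.to_numpy()
    assert np.isfinite(vals).all() and (vals >= 0).all()
    assert (table.provenance[list(POINT_DOMAINS)] == "network").all().all()
    assert (table.provenance[["green", "blue"]] == "raster_median") \
        .all().all()


def test_access_table_matches_per_cell_oracles(small_region):
    """Point-domain cells recomputed one by one with the brute oracle."""
    table = build_access_table(small_region)
    rng = np.random.default_rng(0)
    picks = rng.choice(len(small_region.meshblocks), size=6, replace=False)
    for k in picks:
        mb = small_region.meshblocks[k]
        for d in ("supermarket", "alcohol"):
            want = oracles.brute_network_nearest(
                mb.centroid,
                [tuple(p) for p in small_region.facility_layers[d].points],
                small_region.network)
            assert table.distances.loc[mb.id, d] \
                == pytest.approx(want, abs=1e-6)


def test_facility_at_centroid_gives_zero(small_region):
    import copy
    region = copy.deepcopy(small_region)
    mb = region.meshblocks[7]
    layer = region.facility_layers["supermarket"]
    layer.points = np.vstack([layer.points, mb.centroid])
    table = build_access_table(region)
    assert table.distances.loc[mb.id, "supermarket"] \
        == pytest.approx(0.0, abs=1e-9)
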