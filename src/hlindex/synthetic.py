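"""Synthetic study-region generator.

Produces a fully synthetic geography — meshblock polygons with population,
deprivation deciles and urban/rural classes, a connected road network,
eight facility point layers and green/blue presence rasters — with a
*planted* socio-spatial gradient: with ``gradient_strength > 0``,
health-constraining facilities ('bads') are placed preferentially in more
deprived areas (and supermarkets / physical-activity facilities mildly so),
emulating the empirical pattern that proximity to 'bads' decreases as
area deprivation increases.

Design in brief:

* meshblocks: Voronoi cells of jittered grid points, clipped to a square
  window (mirror trick keeps every cell finite), so cells are convex and
  space-filling like administrative units;
* deprivation: a smooth field (diagonal ramp plus Gaussian bumps) evaluated
  at centroids and rank-cut into equal-count deciles, giving spatially
  autocorrelated deprivation;
* roads: the full Delaunay triangulation over centroids plus jittered
  Steiner points — a dense, connected, planar street mesh with uniform
  detour factors; facilities are placed on the roads, as commercial
  premises front onto streets;
* facilities: stratified systematic draws from a density that increases
  exponentially with local deprivation, strength set by
  ``gradient_strength`` (a gently jittered density-warped lattice — iid
  draws would bury the planted decile gradient in placement noise);
* rasters: green = scattered convex blobs; blue = window-boundary
  "coastline" cells plus one lake blob.

Each layer draws from its own named random substream so adding or removing
one layer never perturbs the others.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Delaunay, Voronoi, cKDTree
from shapely import contains_xy
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .types import (
    BAD_DOMAINS,
    DOMAIN_POLARITY,
    POINT_DOMAINS,
    EnvironmentRaster,
    FacilityLayer,
    GeneratorConfig,
    InputError,
    Meshblock,
    RoadNetwork,
    SyntheticRegion,
)

# named substreams: adding a layer never perturbs the others
_STREAM_CODES = {
    "geometry": 1,
    "dwellings": 2,
    "deprivation": 3,
    "urban": 4,
    "network": 5,
    "raster_green": 6,
    "raster_blue": 7,
    "facility_fast_food": 10,
    "facility_takeaway": 11,
    "facility_dairy_convenience": 12,
    "facility_alcohol": 13,
    "facility_gaming": 14,
    "facility_physical_activity": 15,
    "facility_fruit_veg": 16,
    "facility_supermarket": 17,
}

#: per-domain multiplier on gradient_strength: full for 'bads', mild for
#: supermarkets and physical-activity facilities, neutral otherwise
_DOMAIN_GRADIENT = {
    **{d: 1.0 for d in BAD_DOMAINS},
    "supermarket": 0.4,
    "physical_activity": 0.4,
    "fruit_veg": 0.0,
}

_N_DEP_BUMPS = 6
_DWELLINGS_PER_MESHBLOCK = 6


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed % 2**31, _STREAM_CODES[stream]]))


def population_weighted_centroid(
        dwelling_points: list[tuple[tuple[float, float], float]]
) -> tuple[float, float]:
    """Weighted arithmetic mean of dwelling points.

    The representative point of an area shifted toward where its residents
    live; the origin used for network distances.
    """
    if not dwelling_points:
        raise InputError("population_weighted_centroid: empty dwelling list")
    pts = np.array([p for p, _ in dwelling_points], dtype=float)
    w = np.array([w for _, w in dwelling_points], dtype=float)
    if (w < 0).any():
        raise InputError("population_weighted_centroid: negative weight")
    total = w.sum()
    if total <= 0:
        raise InputError(
            "population_weighted_centroid: all weights zero (degenerate)")
    x, y = (pts * w[:, None]).sum(axis=0) / total
    return (float(x), float(y))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _voronoi_cells(n: int, side: float,
                   rng: np.random.Generator) -> list[Polygon]:
    """n convex Voronoi cells tiling the [0,side]^2 window."""
    g = math.isqrt(n - 1) + 1  # smallest g with g*g >= n
    spacing = side / g
    ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    centers = np.column_stack([(jj.ravel() + 0.5) * spacing,
                               (ii.ravel() + 0.5) * spacing])
    jitter = rng.uniform(-0.35, 0.35, size=centers.shape) * spacing
    pts = centers + jitter
    if len(pts) > n:
        keep = np.sort(rng.choice(len(pts), size=n, replace=False))
        pts = pts[keep]
    # mirror across the four window edges so every original cell is finite
    mirrors = [pts * [-1, 1], pts * [1, -1],
               pts * [-1, 1] + [2 * side, 0], pts * [1, -1] + [0, 2 * side]]
    vor = Voronoi(np.vstack([pts] + mirrors))
    window = box(0.0, 0.0, side, side)
    cells = []
    for k in range(n):
        region = vor.regions[vor.point_region[k]]
        verts = vor.vertices[region]
        # region vertices of a bounded convex cell; order by angle to be safe
        c = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
        poly = Polygon(verts[order]).intersection(window)
        cells.append(poly)
    return cells


def _uniform_points_in_convex(poly: Polygon, k: int,
                              rng: np.random.Generator) -> np.ndarray:
    """k uniform points in a convex polygon via fan triangulation."""
    verts = np.asarray(poly.exterior.coords)[:-1]
    a, b, c = verts[0], verts[1:-1], verts[2:]
    cross = (b[:, 0] - a[0]) * (c[:, 1] - a[1]) \
        - (b[:, 1] - a[1]) * (c[:, 0] - a[0])
    areas = np.abs(cross) / 2.0
    tri = rng.choice(len(areas), size=k, p=areas / areas.sum())
    r1 = np.sqrt(rng.uniform(size=k))
    r2 = rng.uniform(size=k)
    p = (a[None, :] * (1 - r1[:, None])
         + b[tri] * (r1 * (1 - r2))[:, None]
         + c[tri] * (r1 * r2)[:, None])
    return p


# ---------------------------------------------------------------------------
# deprivation field
# ---------------------------------------------------------------------------

class _DeprivationField:
    """Smooth scalar field: diagonal ramp + fixed-substream Gaussian bumps.

    Higher values mean more deprived.  ``normalized`` maps field values to
    [0, 1] using the range observed at the meshblock centroids.
    """

    def __init__(self, side: float, rng: np.random.Generator):
        self.side = side
        self.centers = rng.uniform(0, side, size=(_N_DEP_BUMPS, 2))
        # bumps are kept small relative to the ramp: deprivation then forms
        # contiguous bands with wavy edges and local texture, not closed
        # islands (an island of high deprivation embedded in an affluent
        # neighbourhood would inherit its neighbourhood's sparse facility
        # provision and blur the planted decile gradient)
        self.amps = (rng.uniform(0.02, 0.07, size=_N_DEP_BUMPS)
                     * rng.choice([-1.0, 1.0], size=_N_DEP_BUMPS))
        self.sigmas = rng.uniform(0.1, 0.25, size=_N_DEP_BUMPS) * side
        self._lo = 0.0
        self._hi = 1.0

    def raw(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        val = 1.5 * (xy[:, 0] + xy[:, 1]) / (2 * self.side)
        for c, a, s in zip(self.centers, self.amps, self.sigmas):
            d2 = ((xy - c) ** 2).sum(axis=1)
            val = val + a * np.exp(-d2 / (2 * s * s))
        return val

    def calibrate(self, centroid_xy: np.ndarray) -> np.ndarray:
        vals = self.raw(centroid_xy)
        self._lo, self._hi = float(vals.min()), float(vals.max())
        if self._hi <= self._lo:  # constant field (degenerate): flat
            self._hi = self._lo + 1.0
        return vals

    def normalized(self, xy: np.ndarray) -> np.ndarray:
        v = (self.raw(xy) - self._lo) / (self._hi - self._lo)
        return np.clip(v, 0.0, 1.0)


def _equal_count_deciles(values: np.ndarray, ids: list[str]) -> np.ndarray:
    """Rank ascending (ties by id) and cut into equal-count deciles 1..10."""
    n = len(values)
    order = np.lexsort((np.asarray(ids), values))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return -(-10 * ranks // n)  # ceil(10 r / n)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _urban_rural_classes(centroids: np.ndarray, pops: np.ndarray,
                         side: float, urban_fraction: float,
                         ids: list[str]) -> list[str]:
    """Class by local population density quantile (denser = more urban)."""
    radius = 0.12 * side
    tree = cKDTree(centroids)
    neighbours = tree.query_ball_point(centroids, r=radius)
    density = np.array([pops[idx].sum() for idx in neighbours]) \
        / (math.pi * radius ** 2)
    n = len(ids)
    # densest first; ties broken by id for determinism
    order = np.lexsort((np.asarray(ids), -density))
    n_urban = int(round(urban_fraction * n))
    shares = [0.35, 0.25, 0.20, 0.20]  # of the urban block, densest first
    bounds = np.cumsum([int(round(s * n_urban)) for s in shares])
    bounds[-1] = n_urban
    n_rural = n - n_urban
    settl_end = n_urban + int(round(0.3 * n_rural))
    classes = [""] * n
    for pos, idx in enumerate(order):
        if pos < bounds[0]:
            c = "major_urban"
        elif pos < bounds[1]:
            c = "large_urban"
        elif pos < bounds[2]:
            c = "medium_urban"
        elif pos < bounds[3]:
            c = "small_urban"
        elif pos < settl_end:
            c = "rural_settlement"
        else:
            c = "rural_other"
        classes[idx] = c
    return classes


def _road_network(centroids: np.ndarray, mb_ids: list[str], side: float,
                  rng: np.random.Generator) -> RoadNetwork:
    """Full Delaunay triangulation over centroids plus jittered Steiner
    points: a dense, connected, planar street mesh.  Keeping every
    triangulation edge gives near-Euclidean routing with uniform detour
    factors; sparser prunings make detours erratic enough to blur the
    planted decile gradient.  Every meshblock centroid is itself a node,
    so origin access legs are zero."""
    n_steiner = max(4, len(mb_ids) // 3)
    steiner = rng.uniform(0, side, size=(n_steiner, 2))
    coords = np.vstack([centroids, steiner])
    node_ids = [f"c_{m}" for m in mb_ids] \
        + [f"s_{k:05d}" for k in range(n_steiner)]
    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return RoadNetwork(
        nodes={node_ids[i]: (float(coords[i, 0]), float(coords[i, 1]))
               for i in range(len(coords))},
        edges=[(node_ids[i], node_ids[j],
                float(max(np.linalg.norm(coords[i] - coords[j]), 1e-9)))
               for i, j in sorted(edges)],
    )


_PLACEMENT_GRID = 200
_GRADIENT_SHARPNESS = 5.5  # log-density range at full gradient strength
_STRATUM_JITTER = 0.05     # fraction of a stratum the point may wander


def _place_facilities(domain: str, count: int, side: float,
                      field: _DeprivationField, gradient: float,
                      rng: np.random.Generator) -> FacilityLayer:
    """Sample facility locations with density increasing in deprivation.

    Target density is exp(sharpness * gamma * dep01) on a fine grid
    (uniform when gamma = 0), drawn by two-stage stratified systematic
    sampling: the window is split into ~sqrt(count) equal-weight row
    bands, each band into equal-weight column strata, one jittered point
    per stratum.  Stratification suppresses the clumping noise of
    independent draws, so the planted decile gradient is smooth instead
    of being buried in Poisson placement noise.
    """
    gamma = float(np.clip(gradient * _DOMAIN_GRADIENT[domain], -1.0, 1.0))
    m = _PLACEMENT_GRID
    cell = side / m
    centers_1d = (np.arange(m) + 0.5) * cell
    if gamma == 0.0:
        w = np.ones((m, m))
    else:
        gx, gy = np.meshgrid(centers_1d, centers_1d)
        t = field.normalized(
            np.column_stack([gx.ravel(), gy.ravel()])).reshape(m, m)
        if gamma < 0:
            t = 1.0 - t
        w = np.exp(_GRADIENT_SHARPNESS * abs(gamma) * (t - 1.0))

    # partition rows into ~sqrt(count) contiguous equal-weight bands
    n_bands = max(1, int(round(np.sqrt(count))))
    row_cum = np.cumsum(w.sum(axis=1))
    row_cum /= row_cum[-1]
    band_edges = np.searchsorted(row_cum, np.arange(1, n_bands) / n_bands)
    band_rows = np.split(np.arange(m), np.unique(band_edges) + 1)
    band_rows = [b for b in band_rows if len(b)]
    band_w = np.array([w[b].sum() for b in band_rows])
    # largest-remainder allocation of the count across bands
    quota = count * band_w / band_w.sum()
    alloc = np.floor(quota).astype(int)
    remainder = count - alloc.sum()
    if remainder > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:remainder]] += 1

    pts = []
    for rows, k in zip(band_rows, alloc):
        if k == 0:
            continue
        sub = w[rows]
        col_cum = np.cumsum(sub.sum(axis=0))
        col_cum /= col_cum[-1]
        # near-lattice positions in warped space: centre of each stratum
        # plus a small jitter, so the realised pattern is a gently jittered
        # density-warped grid rather than an independent draw
        u = (np.arange(k) + 0.5
             + rng.uniform(-_STRATUM_JITTER, _STRATUM_JITTER, size=k)) / k
        cols = np.searchsorted(col_cum, u).clip(max=m - 1)
        for j in cols:
            # row within the band: jittered weighted median of the column's
            # weight profile (kept tight for the same reason as above)
            col_cumw = np.cumsum(sub[:, j])
            q = 0.5 + rng.uniform(-_STRATUM_JITTER, _STRATUM_JITTER)
            i = rows[min(int(np.searchsorted(col_cumw, q * col_cumw[-1])),
                         len(rows) - 1)]
            pts.append([
                (j + rng.uniform()) * cell,
                (i + rng.uniform()) * cell,
            ])
    arr = np.array(pts[:count], dtype=float)
    return FacilityLayer(domain=domain, polarity=DOMAIN_POLARITY[domain],
                         points=arr)


def _blob_raster(domain: str, side: float, resolution: float,
                 blobs: list[tuple[np.ndarray, float]],
                 coastline: bool, rng: np.random.Generator
                 ) -> EnvironmentRaster:
    ncells = max(1, math.ceil(side / resolution))
    shape = (ncells, ncells)
    presence = np.zeros(shape, dtype=bool)
    geom = unary_union([Point(c).buffer(r, quad_segs=16) for c, r in blobs])
    xs = (np.arange(ncells) + 0.5) * resolution
    ys = (np.arange(ncells) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)  # gy varies with row: row 0 at bottom
    presence |= contains_xy(geom, gx, gy)
    if coastline:
        presence[0, :] = presence[-1, :] = True
        presence[:, 0] = presence[:, -1] = True
    if not presence.any():  # guarantee the at-least-one-cell invariant
        c = blobs[0][0]
        i = min(int(c[1] // resolution), ncells - 1)
        j = min(int(c[0] // resolution), ncells - 1)
        presence[i, j] = True
    return EnvironmentRaster(domain=domain, origin=(0.0, 0.0),
                             resolution=resolution, presence=presence)


def _project_onto_network(points: np.ndarray,
                          network: RoadNetwork) -> np.ndarray:
    """Nearest point on any road edge, for each input point."""
    _, coords, edge_idx, _ = network.arrays()
    a = coords[edge_idx[:, 0]]
    ab = coords[edge_idx[:, 1]] - a
    ab2 = np.maximum((ab ** 2).sum(axis=1), 1e-18)
    out = np.empty_like(points)
    for lo in range(0, len(points), 256):
        chunk = points[lo:lo + 256]
        ap = chunk[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2, 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d2 = ((chunk[:, None, :] - proj) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        out[lo:lo + 256] = proj[np.arange(len(chunk)), best]
    return out


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def generate_region(config: GeneratorConfig) -> SyntheticRegion:
    """Generate a synthetic region; a pure function of the config (and its
    embedded seed): identical calls reproduce identical regions."""
    n, side, seed = config.n_meshblocks, config.window_side, config.seed

    cells = _voronoi_cells(n, side, _rng(seed, "geometry"))
    mb_ids = [f"mb{k:05d}" for k in range(n)]

    dw_rng = _rng(seed, "dwellings")
    pops = dw_rng.integers(60, 121, size=n)
    centroids = np.empty((n, 2))
    for k, poly in enumerate(cells):
        dw = _uniform_points_in_convex(poly, _DWELLINGS_PER_MESHBLOCK, dw_rng)
        weights = dw_rng.multinomial(
            int(pops[k]), [1 / len(dw)] * len(dw)).astype(float)
        if weights.sum() == 0:  # unreachable for pops >= 60; safety net
            weights[:] = 1.0
        centroids[k] = population_weighted_centroid(
            [((p[0], p[1]), w) for p, w in zip(dw, weights)])

    field = _DeprivationField(side, _rng(seed, "deprivation"))
    dep_values = field.calibrate(centroids)
    dep_deciles = _equal_count_deciles(dep_values, mb_ids)

    classes = _urban_rural_classes(centroids, pops, side,
                                   config.urban_fraction, mb_ids)

    meshblocks = [
        Meshblock(id=mb_ids[k], polygon=cells[k], population=int(pops[k]),
                  centroid=(float(centroids[k, 0]), float(centroids[k, 1])),
                  dep_decile=int(dep_deciles[k]), urban_rural=classes[k])
        for k in range(n)
    ]

    network = _road_network(centroids, mb_ids, side, _rng(seed, "network"))

    layers = {
        d: _place_facilities(d, config.facilities_per_domain, side, field,
                             config.gradient_strength,
                             _rng(seed, f"facility_{d}"))
        for d in POINT_DOMAINS
    }
    # commercial premises front onto streets: move each facility to its
    # nearest point on the road network (also removes the facility access
    # leg from every reported distance)
    for layer in layers.values():
        layer.points = _project_onto_network(layer.points, network)

    g_rng = _rng(seed, "raster_green")
    n_green = max(6, n // 60)
    green_blobs = [(g_rng.uniform(0, side, size=2),
                    g_rng.uniform(0.015, 0.05) * side)
                   for _ in range(n_green)]
    green = _blob_raster("green", side, config.resolution, green_blobs,
                         coastline=False, rng=g_rng)

    b_rng = _rng(seed, "raster_blue")
    lake = [(b_rng.uniform(0.2 * side, 0.8 * side, size=2),
             b_rng.uniform(0.03, 0.06) * side)]
    blue = _blob_raster("blue", side, config.resolution, lake,
                        coastline=True, rng=b_rng)

    region = SyntheticRegion(meshblocks=meshblocks, network=network,
                             facility_layers=layers,
                             rasters={"green": green, "blue": blue},
                             params=config, seed=seed)
    region.validate()
    return region
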