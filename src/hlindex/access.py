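"""Accessibility metrics: the meshblock x 10-domain distance table.

For the eight facility domains the metric is road-network distance (km)
from the meshblock's population-weighted centroid to the nearest facility:
both the centroid and every facility are snapped to their nearest point on
the network, edges are split at the snap points, and the straight-line
access legs onto the network are included in the total (this keeps the
facility-at-centroid distance exactly zero and prevents free teleportation
onto the network).  If a centroid cannot reach any facility of a domain
(disconnected user-supplied network), the straight-line distance is used
instead and the cell is flagged ``euclidean_fallback``.

Green and blue space are area phenomena: they are handled on a 50 m
presence raster via a Euclidean distance transform, and each meshblock's
access is the *median* of the distance-transform values over the cells
whose centres fall inside the meshblock ("median proximity from any place
in the meshblock").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .types import (
    DOMAIN_ORDER,
    POINT_DOMAINS,
    PROVENANCE_EUCLIDEAN,
    PROVENANCE_NETWORK,
    PROVENANCE_RASTER,
    RASTER_DOMAINS,
    AccessTable,
    DistanceGrid,
    EnvironmentRaster,
    InputError,
    Meshblock,
    NetworkLocation,
    RoadNetwork,
    SyntheticRegion,
)

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

def _snap_arrays(points: np.ndarray, network: RoadNetwork):
    """Snap each point to its nearest edge.

    Returns (edge_index, offset_m, access_offset_m) arrays.  Ties in snap
    distance are broken by the lexicographically smallest (u, v) node-id
    pair, which is the first edge in the network's canonical edge order.
    """
    node_ids, coords, edge_idx, lengths = network.arrays()
    if len(edge_idx) == 0:
        raise InputError("snap_to_network: network has no edges")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = coords[edge_idx[:, 0]]
    ab = coords[edge_idx[:, 1]] - a
    ab2 = np.maximum((ab ** 2).sum(axis=1), 1e-18)

    out_edge = np.empty(len(pts), dtype=int)
    out_off = np.empty(len(pts))
    out_acc = np.empty(len(pts))
    for lo in range(0, len(pts), 256):
        chunk = pts[lo:lo + 256]
        ap = chunk[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2, 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d = np.linalg.norm(chunk[:, None, :] - proj, axis=2)
        dmin = d.min(axis=1)
        # first edge within tolerance of the minimum = lexicographic winner
        best = np.argmax(d <= dmin[:, None] + _TIE_TOL, axis=1)
        sel = np.arange(len(chunk))
        out_edge[lo:lo + 256] = best
        out_off[lo:lo + 256] = t[sel, best] * lengths[best]
        out_acc[lo:lo + 256] = d[sel, best]
    return out_edge, out_off, out_acc


def snap_to_network(point: tuple[float, float],
                    network: RoadNetwork) -> NetworkLocation:
    """Nearest point on any network edge (perpendicular projection clamped
    to the endpoints)."""
    if not network.nodes or not network.edges:
        raise InputError("snap_to_network: empty network")
    e, off, acc = _snap_arrays(np.array([point]), network)
    u, v, _ = network.edges[e[0]]
    return NetworkLocation(edge=(u, v), offset=float(off[0]),
                           access_offset=float(acc[0]))


# ---------------------------------------------------------------------------
# shortest paths on the split graph
# ---------------------------------------------------------------------------

def _split_graph(network: RoadNetwork, snap_edges: np.ndarray,
                 snap_offsets: np.ndarray):
    """Subdivide edges at snap points.

    Returns (csr graph, total node count, snap-node index per snap point).
    Original nodes keep indices 0..V-1; each snap point becomes its own
    node even when offsets coincide (joined by zero-length sub-edges).
    """
    node_ids, _, edge_idx, lengths = network.arrays()
    V = len(node_ids)
    snap_node = V + np.arange(len(snap_edges))
    n_nodes = V + len(snap_edges)

    # dict accumulation keeps the *minimum* weight for parallel entries and
    # lets zero-length sub-edges survive CSR construction as tiny positives
    weights: dict[tuple[int, int], float] = {}

    def add(i: int, j: int, w: float) -> None:
        w = max(w, 1e-300)  # exact zeros would be dropped by the CSR format
        key = (i, j) if i <= j else (j, i)
        if key not in weights or w < weights[key]:
            weights[key] = w

    by_edge: dict[int, list[int]] = {}
    for s, e in enumerate(snap_edges):
        by_edge.setdefault(int(e), []).append(s)

    plain = np.ones(len(edge_idx), dtype=bool)
    for e, snaps in by_edge.items():
        plain[e] = False
        order = sorted(snaps, key=lambda s: (snap_offsets[s], s))
        chain = [int(edge_idx[e, 0])] + [int(snap_node[s]) for s in order] \
            + [int(edge_idx[e, 1])]
        offs = [0.0] + [float(snap_offsets[s]) for s in order] \
            + [float(lengths[e])]
        for k in range(len(chain) - 1):
            add(chain[k], chain[k + 1], offs[k + 1] - offs[k])
    for e in np.flatnonzero(plain):
        add(int(edge_idx[e, 0]), int(edge_idx[e, 1]), float(lengths[e]))
    keys = np.array(list(weights), dtype=int).reshape(-1, 2)
    g = csr_matrix((np.array(list(weights.values())),
                    (keys[:, 0], keys[:, 1])),
                   shape=(n_nodes, n_nodes))
    return g, n_nodes, snap_node


def _nearest_via_network(origins: np.ndarray, facilities: np.ndarray,
                         network: RoadNetwork,
                         origin_snaps=None) -> np.ndarray:
    """Distance (m) from each origin to its nearest facility along the
    network, access legs included; inf where unreachable.

    ``origin_snaps`` may carry precomputed snap arrays for the origins so
    batch callers snap their centroids only once.
    """
    if origin_snaps is None:
        o_edge, o_off, o_acc = _snap_arrays(origins, network)
    else:
        o_edge, o_off, o_acc = origin_snaps
    f_edge, f_off, f_acc = _snap_arrays(facilities, network)
    all_edges = np.concatenate([o_edge, f_edge])
    all_offs = np.concatenate([o_off, f_off])
    g, n_nodes, snap_node = _split_graph(network, all_edges, all_offs)
    o_nodes = snap_node[: len(origins)]
    f_nodes = snap_node[len(origins):]

    # super-source wired to every facility snap with its access leg as the
    # edge weight -> one Dijkstra gives nearest-facility distance everywhere
    from scipy.sparse import vstack, hstack, csr_matrix as csr
    super_row = np.zeros((1, n_nodes))
    super_row[0, f_nodes] = np.where(f_acc > 0, f_acc, 1e-300)
    gg = vstack([hstack([g, csr((n_nodes, 1))]),
                 csr(np.hstack([super_row, [[0.0]]]))]).tocsr()
    d = dijkstra(gg, directed=False, indices=n_nodes)
    return d[o_nodes] + o_acc


def euclidean_nearest_distance(origin: tuple[float, float],
                               facilities: np.ndarray) -> float:
    """Minimum straight-line distance origin -> facilities, km."""
    facilities = np.asarray(facilities, dtype=float).reshape(-1, 2)
    if len(facilities) == 0:
        raise InputError("euclidean_nearest_distance: empty facility list")
    d = np.linalg.norm(facilities - np.asarray(origin, dtype=float), axis=1)
    return float(d.min()) / 1000.0


def network_nearest_distance(origin: tuple[float, float],
                             facilities: np.ndarray,
                             network: RoadNetwork) -> float:
    """Road-network distance (km) from origin to the nearest facility.

    Total = origin access leg + shortest path between snap points (edges
    split at the snap offsets) + facility access leg.  Falls back to the
    straight-line distance (with a warning) when no facility is reachable.
    """
    facilities = np.asarray(facilities, dtype=float).reshape(-1, 2)
    if len(facilities) == 0:
        raise InputError("network_nearest_distance: empty facility list")
    d = _nearest_via_network(np.array([origin], dtype=float),
                             facilities, network)[0]
    if not np.isfinite(d):
        logger.warning("origin unreachable from all facilities; "
                       "euclidean fallback used")
        return euclidean_nearest_distance(origin, facilities)
    return float(d) / 1000.0


# ---------------------------------------------------------------------------
# raster pipeline (green / blue)
# ---------------------------------------------------------------------------

def rasterize_features(polygons, window, resolution: float = 50.0,
                       domain: str = "green") -> EnvironmentRaster:
    """Burn polygons onto a boolean grid: a cell is true iff its centre
    lies inside any polygon (centre-in-polygon rule)."""
    if isinstance(window, BaseGeometry):
        xmin, ymin, xmax, ymax = window.bounds
    else:
        xmin, ymin, xmax, ymax = window
    if not (xmax > xmin and ymax > ymin):
        raise InputError("rasterize_features: zero-area window")
    ncols = int(np.ceil((xmax - xmin) / resolution))
    nrows = int(np.ceil((ymax - ymin) / resolution))
    geom = unary_union(list(polygons))
    xs = xmin + (np.arange(ncols) + 0.5) * resolution
    ys = ymin + (np.arange(nrows) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    presence = contains_xy(geom, gx, gy)
    return EnvironmentRaster(domain=domain, origin=(xmin, ymin),
                             resolution=resolution, presence=presence)


def distance_transform(raster: EnvironmentRaster) -> DistanceGrid:
    """Per-cell Euclidean distance (m, centre to centre) to the nearest
    presence cell."""
    if not raster.presence.any():
        raise InputError(
            f"distance_transform: raster {raster.domain} has no true cells")
    values = distance_transform_edt(~raster.presence,
                                    sampling=raster.resolution)
    return DistanceGrid(domain=raster.domain, origin=raster.origin,
                        resolution=raster.resolution,
                        values=np.asarray(values, dtype=float))


def median_proximity(meshblock: Meshblock, grid: DistanceGrid) -> float:
    """Median of distance-grid values over cells whose centres fall inside
    the meshblock, km; a meshblock too small to contain any cell centre
    takes the value of the cell containing its centroid."""
    nrows, ncols = grid.values.shape
    x0, y0 = grid.origin
    res = grid.resolution
    xmin, ymin, xmax, ymax = meshblock.polygon.bounds
    j0 = max(int((xmin - x0) // res), 0)
    j1 = min(int((xmax - x0) // res) + 1, ncols)
    i0 = max(int((ymin - y0) // res), 0)
    i1 = min(int((ymax - y0) // res) + 1, nrows)
    if j1 > j0 and i1 > i0:
        xs = x0 + (np.arange(j0, j1) + 0.5) * res
        ys = y0 + (np.arange(i0, i1) + 0.5) * res
        gx, gy = np.meshgrid(xs, ys)
        inside = contains_xy(meshblock.polygon, gx, gy)
        if inside.any():
            return float(np.median(grid.values[i0:i1, j0:j1][inside])) / 1000.0
    cx, cy = meshblock.centroid
    ci = int((cy - y0) // res)
    cj = int((cx - x0) // res)
    if not (0 <= ci < nrows and 0 <= cj < ncols):
        raise InputError(
            f"median_proximity: centroid of {meshblock.id} outside grid")
    return float(grid.values[ci, cj]) / 1000.0


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_access_table(region: SyntheticRegion) -> AccessTable:
    """Compute the complete 10-domain access table for a region."""
    region.validate()
    ids = [mb.id for mb in region.meshblocks]
    centroids = np.array([mb.centroid for mb in region.meshblocks])
    dist = pd.DataFrame(index=pd.Index(ids, name="meshblock_id"),
                        columns=list(DOMAIN_ORDER), dtype=float)
    prov = pd.DataFrame(index=dist.index, columns=list(DOMAIN_ORDER),
                        dtype=object)

    origin_snaps = _snap_arrays(centroids, region.network)
    for d in POINT_DOMAINS:
        pts = region.facility_layers[d].points
        try:
            metres = _nearest_via_network(centroids, pts, region.network,
                                          origin_snaps=origin_snaps)
        except InputError as exc:
            raise InputError(f"domain {d}: {exc}") from exc
        km = metres / 1000.0
        fallback = ~np.isfinite(km)
        if fallback.any():
            logger.warning("domain %s: %d meshblock(s) unreachable; "
                           "euclidean fallback", d, int(fallback.sum()))
            for k in np.flatnonzero(fallback):
                km[k] = euclidean_nearest_distance(tuple(centroids[k]), pts)
        dist[d] = km
        prov[d] = np.where(fallback, PROVENANCE_EUCLIDEAN, PROVENANCE_NETWORK)

    for d in RASTER_DOMAINS:
        grid = distance_transform(region.rasters[d])
        col = np.empty(len(ids))
        for k, mb in enumerate(region.meshblocks):
            try:
                col[k] = median_proximity(mb, grid)
            except InputError as exc:
                raise InputError(f"meshblock {mb.id}, domain {d}: {exc}") \
                    from exc
        dist[d] = col
        prov[d] = PROVENANCE_RASTER

    table = AccessTable(distances=dist, provenance=prov)
    table.validate()
    return table
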