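"""Domain types, constants and errors for the Healthy Location Index (HLI).

The HLI describes each small area ("meshblock", the smallest census unit,
~60-120 residents) by its access to ten environmental domains: five
health-promoting 'goods' (green space, blue space, physical-activity
facilities, fruit/vegetable outlets, supermarkets) and five
health-constraining 'bads' (fast food, takeaway, dairy/convenience,
alcohol, gaming).  All geometry is planar, in metres; distances are
reported in kilometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

# ---------------------------------------------------------------------------
# Domain vocabulary
# ---------------------------------------------------------------------------

GOOD_DOMAINS: tuple[str, ...] = (
    "green", "blue", "physical_activity", "fruit_veg", "supermarket",
)
BAD_DOMAINS: tuple[str, ...] = (
    "fast_food", "takeaway", "dairy_convenience", "alcohol", "gaming",
)
#: point-based facility domains (network distance from the meshblock centroid)
POINT_DOMAINS: tuple[str, ...] = (
    "fast_food", "takeaway", "dairy_convenience", "alcohol", "gaming",
    "physical_activity", "fruit_veg", "supermarket",
)
#: area phenomena stored as 50 m presence rasters (median proximity metric)
RASTER_DOMAINS: tuple[str, ...] = ("green", "blue")

#: fixed, documented column order for all tables (bads then goods)
DOMAIN_ORDER: tuple[str, ...] = (
    "fast_food", "takeaway", "dairy_convenience", "alcohol", "gaming",
    "physical_activity", "fruit_veg", "green", "blue", "supermarket",
)

DOMAIN_POLARITY: dict[str, str] = {
    **{d: "good" for d in GOOD_DOMAINS},
    **{d: "bad" for d in BAD_DOMAINS},
}

URBAN_RURAL_CLASSES: tuple[str, ...] = (
    "major_urban", "large_urban", "medium_urban", "small_urban",
    "rural_settlement", "rural_other",
)

#: nominal mean meshblock footprint used to size the synthetic study window
MESHBLOCK_AREA_M2: float = 250_000.0

DEFAULT_RESOLUTION_M: float = 50.0

PROVENANCE_NETWORK = "network"
PROVENANCE_EUCLIDEAN = "euclidean_fallback"
PROVENANCE_RASTER = "raster_median"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class HLIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HLIError):
    """A configuration value is out of its documented bounds."""


class InputError(HLIError):
    """An operation received degenerate or invalid input."""


class LoadError(HLIError):
    """A required file or layer is missing or unreadable."""


class ValidationError(HLIError):
    """One or more type invariants are violated; lists every violation."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s): "
            + "; ".join(self.problems)
        )


# ---------------------------------------------------------------------------
# Geography types
# ---------------------------------------------------------------------------

@dataclass
class Meshblock:
    """A small-area unit: polygon, residents, and attributes.

    ``centroid`` is the population-weighted centroid (the weighted mean of
    the unit's dwelling points), the origin for network distances.
    ``dep_decile`` is an area deprivation decile, 1 = least deprived,
    10 = most deprived.
    """

    id: str
    polygon: Polygon
    population: int
    centroid: tuple[float, float]
    dep_decile: int
    urban_rural: str

    def problems(self) -> list[str]:
        out = []
        if not isinstance(self.polygon, Polygon) or self.polygon.is_empty:
            out.append(f"meshblock {self.id}: polygon empty or not a polygon")
        elif not self.polygon.is_valid:
            out.append(f"meshblock {self.id}: polygon is not simple/valid")
        if self.population < 0:
            out.append(f"meshblock {self.id}: negative population "
                       f"{self.population}")
        if not (1 <= self.dep_decile <= 10):
            out.append(f"meshblock {self.id}: dep_decile {self.dep_decile} "
                       "outside 1..10")
        if self.urban_rural not in URBAN_RURAL_CLASSES:
            out.append(f"meshblock {self.id}: unknown urban_rural class "
                       f"{self.urban_rural!r}")
        if (isinstance(self.polygon, Polygon) and not self.polygon.is_empty
                and not self.polygon.buffer(1e-9).contains(
                    Point(self.centroid))):
            out.append(f"meshblock {self.id}: centroid outside polygon")
        return out


@dataclass
class RoadNetwork:
    """Undirected road graph: node id -> (x, y) metres, edges with lengths.

    Edges are stored canonically with the lexicographically smaller node id
    first; this ordering is also the tie-break key for snapping.
    """

    nodes: dict[str, tuple[float, float]]
    edges: list[tuple[str, str, float]]
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.edges = [
            (u, v, length) if u <= v else (v, u, length)
            for u, v, length in self.edges
        ]
        self.edges.sort(key=lambda e: (e[0], e[1]))

    def problems(self) -> list[str]:
        out = []
        for u, v, length in self.edges:
            if u not in self.nodes or v not in self.nodes:
                out.append(f"edge ({u},{v}) references a missing node")
            if not length > 0:
                out.append(f"edge ({u},{v}) has non-positive length {length}")
        return out

    def arrays(self):
        """(node_ids, coords[V,2], edge_idx[E,2], lengths[E]) with node ids
        sorted ascending; cached."""
        if "arrays" not in self._cache:
            node_ids = sorted(self.nodes)
            index = {n: i for i, n in enumerate(node_ids)}
            coords = np.array([self.nodes[n] for n in node_ids], dtype=float)
            if self.edges:
                edge_idx = np.array(
                    [(index[u], index[v]) for u, v, _ in self.edges], dtype=int)
                lengths = np.array([l for _, _, l in self.edges], dtype=float)
            else:
                edge_idx = np.empty((0, 2), dtype=int)
                lengths = np.empty(0, dtype=float)
            self._cache["arrays"] = (node_ids, coords, edge_idx, lengths)
        return self._cache["arrays"]

    def is_connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components
        node_ids, _, edge_idx, lengths = self.arrays()
        if len(node_ids) <= 1:
            return True
        from scipy.sparse import coo_matrix
        m = coo_matrix(
            (lengths, (edge_idx[:, 0], edge_idx[:, 1])),
            shape=(len(node_ids), len(node_ids)))
        n_comp, _ = connected_components(m, directed=False)
        return n_comp == 1


@dataclass
class FacilityLayer:
    """Point locations of one facility domain, with good/bad polarity."""

    domain: str
    polarity: str
    points: np.ndarray  # (k, 2) metres

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def problems(self) -> list[str]:
        out = []
        if self.domain not in POINT_DOMAINS:
            out.append(f"facility layer: unknown domain {self.domain!r}")
        elif self.polarity != DOMAIN_POLARITY[self.domain]:
            out.append(f"facility layer {self.domain}: polarity "
                       f"{self.polarity!r} but this domain is "
                       f"{DOMAIN_POLARITY[self.domain]!r}")
        if len(self.points) == 0:
            out.append(f"facility layer {self.domain}: no points")
        return out

    def __eq__(self, other) -> bool:  # ndarray needs explicit comparison
        return (isinstance(other, FacilityLayer)
                and self.domain == other.domain
                and self.polarity == other.polarity
                and np.array_equal(self.points, other.points))


@dataclass
class EnvironmentRaster:
    """Boolean presence grid for green or blue cover.

    Row-major with cell (0, 0) at the origin (lower-left) corner; the centre
    of cell (i, j) is ``origin + ((j + 0.5) * res, (i + 0.5) * res)``.
    """

    domain: str
    origin: tuple[float, float]
    resolution: float
    presence: np.ndarray  # (nrows, ncols) bool

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)

    def problems(self) -> list[str]:
        out = []
        if self.domain not in RASTER_DOMAINS:
            out.append(f"raster: unknown domain {self.domain!r}")
        if not self.resolution > 0:
            out.append(f"raster {self.domain}: non-positive resolution")
        if not self.presence.any():
            out.append(f"raster {self.domain}: no presence cells")
        return out

    def cell_centers(self):
        """(xs[ncols], ys[nrows]) of cell-centre coordinates."""
        nrows, ncols = self.presence.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.resolution
        ys = self.origin[1] + (np.arange(nrows) + 0.5) * self.resolution
        return xs, ys

    def __eq__(self, other) -> bool:
        return (isinstance(other, EnvironmentRaster)
                and self.domain == other.domain
                and self.origin == other.origin
                and self.resolution == other.resolution
                and np.array_equal(self.presence, other.presence))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic region generator.

    gradient_strength in [-1, 1] plants the association between deprivation
    and proximity to 'bads' (positive: bads are closer in deprived areas,
    as observed empirically); 0 means placement independent of deprivation.
    """

    n_meshblocks: int = 500
    urban_fraction: float = 0.7
    gradient_strength: float = 0.8
    facilities_per_domain: int | None = None
    seed: int = 0
    resolution: float = DEFAULT_RESOLUTION_M

    def __post_init__(self) -> None:
        if self.facilities_per_domain is None:
            # facility provision scales with settlement size: one outlet
            # per ~5 meshblocks (a few hundred residents), the density of
            # common urban outlet types in national registers
            object.__setattr__(self, "facilities_per_domain",
                               max(8, self.n_meshblocks // 5))
        if self.n_meshblocks < 20:
            raise ConfigurationError(
                f"n_meshblocks must be >= 20, got {self.n_meshblocks}")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ConfigurationError(
                f"urban_fraction must be in [0, 1], got {self.urban_fraction}")
        if not (-1.0 <= self.gradient_strength <= 1.0):
            raise ConfigurationError(
                "gradient_strength must be in [-1, 1], got "
                f"{self.gradient_strength}")
        if self.facilities_per_domain < 1:
            raise ConfigurationError(
                "facilities_per_domain must be >= 1, got "
                f"{self.facilities_per_domain}")
        if not self.resolution > 0:
            raise ConfigurationError(
                f"resolution must be > 0, got {self.resolution}")

    @property
    def window_side(self) -> float:
        """Side length (m) of the square study window."""
        return math.sqrt(self.n_meshblocks * MESHBLOCK_AREA_M2)


@dataclass
class SyntheticRegion:
    """A complete synthetic study region (10 environmental domains)."""

    meshblocks: list[Meshblock]
    network: RoadNetwork
    facility_layers: dict[str, FacilityLayer]
    rasters: dict[str, EnvironmentRaster]
    params: GeneratorConfig
    seed: int

    @property
    def window(self) -> tuple[float, float, float, float]:
        s = self.params.window_side
        return (0.0, 0.0, s, s)

    def problems(self) -> list[str]:
        out = []
        for mb in self.meshblocks:
            out.extend(mb.problems())
        out.extend(self.network.problems())
        missing = set(POINT_DOMAINS) - set(self.facility_layers)
        for d in sorted(missing):
            out.append(f"missing facility layer: {d}")
        for layer in self.facility_layers.values():
            out.extend(layer.problems())
        for d in RASTER_DOMAINS:
            if d not in self.rasters:
                out.append(f"missing raster: {d}")
        for r in self.rasters.values():
            out.extend(r.problems())
        ids = [mb.id for mb in self.meshblocks]
        if len(set(ids)) != len(ids):
            out.append("duplicate meshblock ids")
        return out

    def validate(self) -> None:
        problems = self.problems()
        if problems:
            raise ValidationError(problems)

    def meshblock_frame(self):
        """Meshblock attributes as a DataFrame indexed by id."""
        import pandas as pd
        return pd.DataFrame(
            {
                "population": [mb.population for mb in self.meshblocks],
                "dep_decile": [mb.dep_decile for mb in self.meshblocks],
                "urban_rural": [mb.urban_rural for mb in self.meshblocks],
                "centroid_x": [mb.centroid[0] for mb in self.meshblocks],
                "centroid_y": [mb.centroid[1] for mb in self.meshblocks],
            },
            index=pd.Index([mb.id for mb in self.meshblocks],
                           name="meshblock_id"),
        )


# ---------------------------------------------------------------------------
# Accessibility types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkLocation:
    """A point snapped onto a network edge.

    ``offset`` is measured in metres along the edge from its first
    (lexicographically smaller) node; ``access_offset`` is the straight-line
    distance from the original point to the snap point.
    """

    edge: tuple[str, str]
    offset: float
    access_offset: float


@dataclass
class DistanceGrid:
    """Per-cell Euclidean distance (m) to the nearest presence cell."""

    domain: str
    origin: tuple[float, float]
    resolution: float
    values: np.ndarray  # (nrows, ncols) float metres

    def cell_centers(self):
        nrows, ncols = self.values.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.resolution
        ys = self.origin[1] + (np.arange(nrows) + 0.5) * self.resolution
        return xs, ys


@dataclass
class AccessTable:
    """Meshblock x 10-domain matrix of distances (km) with provenance flags.

    ``distances`` and ``provenance`` share index (meshblock id) and columns
    (:data:`DOMAIN_ORDER`); provenance values are ``network``,
    ``euclidean_fallback`` or ``raster_median``.
    """

    distances: "pd.DataFrame"  # noqa: F821 - annotation only
    provenance: "pd.DataFrame"  # noqa: F821

    def validate(self) -> None:
        problems = []
        if list(self.distances.columns) != list(DOMAIN_ORDER):
            problems.append("distance columns not in documented domain order")
        vals = self.distances.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.distances.index[~np.isfinite(vals).all(axis=1)]
            problems.append(f"non-finite distances for ids {list(bad)}")
        elif (vals < 0).any():
            problems.append("negative distances present")
        for d in POINT_DOMAINS:
            ok = self.provenance[d].isin(
                [PROVENANCE_NETWORK, PROVENANCE_EUCLIDEAN]).all()
            if not ok:
                problems.append(f"bad provenance flag in point domain {d}")
        for d in RASTER_DOMAINS:
            if not (self.provenance[d] == PROVENANCE_RASTER).all():
                problems.append(f"bad provenance flag in raster domain {d}")
        if problems:
            raise ValidationError(problems)
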