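"""File formats, configuration and the end-to-end pipeline.

Layout of a region directory (all open text formats):

* ``meshblocks.geojson`` — polygons with id, population, dep_decile,
  urban_rural and the population-weighted centroid as properties;
* ``facilities_<domain>.geojson`` — one point layer per facility domain
  with its polarity;
* ``network_nodes.geojson`` + ``network_edges.csv`` — road graph;
* ``raster_green.asc`` / ``raster_blue.asc`` — Esri ASCII presence grids;
* ``region.json`` — the generator config and seed.

``run_pipeline`` chains simulate (or load) -> access -> index -> summarise
and records a manifest (seed, config hash, per-stage row counts); a rerun
with an identical config reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .access import build_access_table
from .index import HLIResult, compute_hli
from .summary import (
    goods_bads_rank_correlation,
    median_distance_by_deprivation,
    plot_rank_scatter,
    plot_share_bars,
    population_share_by_hli,
)
from .synthetic import generate_region
from .types import (
    BAD_DOMAINS,
    DOMAIN_ORDER,
    DOMAIN_POLARITY,
    GOOD_DOMAINS,
    POINT_DOMAINS,
    RASTER_DOMAINS,
    AccessTable,
    ConfigurationError,
    EnvironmentRaster,
    FacilityLayer,
    GeneratorConfig,
    HLIError,
    LoadError,
    Meshblock,
    RoadNetwork,
    SyntheticRegion,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# region I/O
# ---------------------------------------------------------------------------

def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def write_region(region: SyntheticRegion, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    features = []
    for mb in region.meshblocks:
        features.append({
            "type": "Feature",
            "geometry": mapping(mb.polygon),
            "properties": {
                "id": mb.id, "population": mb.population,
                "dep_decile": mb.dep_decile, "urban_rural": mb.urban_rural,
                "centroid_x": mb.centroid[0], "centroid_y": mb.centroid[1],
            },
        })
    _dump_json({"type": "FeatureCollection", "features": features},
               directory / "meshblocks.geojson")

    for d, layer in sorted(region.facility_layers.items()):
        feats = [{"type": "Feature",
                  "geometry": {"type": "Point",
                               "coordinates": [float(x), float(y)]},
                  "properties": {"domain": d, "polarity": layer.polarity}}
                 for x, y in layer.points]
        _dump_json({"type": "FeatureCollection", "features": feats},
                   directory / f"facilities_{d}.geojson")

    node_feats = [{"type": "Feature",
                   "geometry": {"type": "Point",
                                "coordinates": [x, y]},
                   "properties": {"id": nid}}
                  for nid, (x, y) in sorted(region.network.nodes.items())]
    _dump_json({"type": "FeatureCollection", "features": node_feats},
               directory / "network_nodes.geojson")
    edges = pd.DataFrame(region.network.edges, columns=["u", "v", "length_m"])
    edges.to_csv(directory / "network_edges.csv", index=False)

    for d, raster in sorted(region.rasters.items()):
        _write_ascii_grid(raster, directory / f"raster_{d}.asc")

    _dump_json({"seed": region.seed,
                "params": dataclasses.asdict(region.params)},
               directory / "region.json")


def _write_ascii_grid(raster: EnvironmentRaster, path: Path) -> None:
    nrows, ncols = raster.presence.shape
    lines = [f"ncols {ncols}", f"nrows {nrows}",
             f"xllcorner {raster.origin[0]!r}",
             f"yllcorner {raster.origin[1]!r}",
             f"cellsize {raster.resolution!r}", "NODATA_value -9999"]
    grid = np.flipud(raster.presence.astype(int))  # .asc rows run top-down
    lines.extend(" ".join(map(str, row)) for row in grid)
    path.write_text("\n".join(lines) + "\n")


def _read_ascii_grid(path: Path, domain: str) -> EnvironmentRaster:
    lines = path.read_text().splitlines()
    header = {}
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = val
    data = np.loadtxt(lines[6:], dtype=int)
    data = np.atleast_2d(data)
    return EnvironmentRaster(
        domain=domain,
        origin=(float(header["xllcorner"]), float(header["yllcorner"])),
        resolution=float(header["cellsize"]),
        presence=np.flipud(data.astype(bool)))


def read_region(directory: str | Path) -> SyntheticRegion:
    """Load and validate a region directory.

    Missing layers raise :class:`LoadError` naming the layer; invariant
    violations are collected across the whole region and raised together
    as one :class:`ValidationError`.
    """
    directory = Path(directory)
    mb_path = directory / "meshblocks.geojson"
    if not mb_path.exists():
        raise LoadError("missing layer: meshblocks")
    fc = json.loads(mb_path.read_text())
    meshblocks = []
    for feat in fc["features"]:
        props = feat["properties"]
        meshblocks.append(Meshblock(
            id=props["id"], polygon=shape(feat["geometry"]),
            population=int(props["population"]),
            centroid=(props["centroid_x"], props["centroid_y"]),
            dep_decile=int(props["dep_decile"]),
            urban_rural=props["urban_rural"]))

    layers = {}
    for d in POINT_DOMAINS:
        p = directory / f"facilities_{d}.geojson"
        if not p.exists():
            raise LoadError(f"missing layer: {d}")
        fc = json.loads(p.read_text())
        pts = np.array([f["geometry"]["coordinates"] for f in fc["features"]],
                       dtype=float).reshape(-1, 2)
        polarity = (fc["features"][0]["properties"]["polarity"]
                    if fc["features"] else DOMAIN_POLARITY[d])
        layers[d] = FacilityLayer(domain=d, polarity=polarity, points=pts)

    nodes_path = directory / "network_nodes.geojson"
    edges_path = directory / "network_edges.csv"
    if not nodes_path.exists() or not edges_path.exists():
        raise LoadError("missing layer: network")
    fc = json.loads(nodes_path.read_text())
    nodes = {f["properties"]["id"]: tuple(f["geometry"]["coordinates"])
             for f in fc["features"]}
    edges_df = pd.read_csv(edges_path, float_precision="round_trip")
    edges = [(str(r.u), str(r.v), float(r.length_m))
             for r in edges_df.itertuples()]
    network = RoadNetwork(nodes=nodes, edges=edges)

    rasters = {}
    for d in RASTER_DOMAINS:
        p = directory / f"raster_{d}.asc"
        if not p.exists():
            raise LoadError(f"missing layer: {d}")
        rasters[d] = _read_ascii_grid(p, d)

    meta_path = directory / "region.json"
    if not meta_path.exists():
        raise LoadError("missing layer: region.json")
    meta = json.loads(meta_path.read_text())
    params = GeneratorConfig(**meta["params"])
    region = SyntheticRegion(meshblocks=meshblocks, network=network,
                             facility_layers=layers, rasters=rasters,
                             params=params, seed=meta["seed"])
    region.validate()
    return region


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def write_access_table(table: AccessTable, path: str | Path) -> None:
    out = table.distances.copy()
    for d in DOMAIN_ORDER:
        out[f"prov_{d}"] = table.provenance[d]
    out.to_csv(path)


def read_access_table(path: str | Path) -> AccessTable:
    df = pd.read_csv(path, index_col="meshblock_id",
                     float_precision="round_trip")
    missing = [d for d in DOMAIN_ORDER if d not in df.columns]
    if missing:
        raise LoadError(f"access table missing domain columns {missing}")
    dist = df[list(DOMAIN_ORDER)].astype(float)
    prov = df[[f"prov_{d}" for d in DOMAIN_ORDER]].copy()
    prov.columns = list(DOMAIN_ORDER)
    table = AccessTable(distances=dist, provenance=prov)
    table.validate()
    return table


def write_hli(result: HLIResult, path: str | Path) -> None:
    result.to_frame().to_csv(path)


def read_hli(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="meshblock_id")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; all randomness flows from ``generator.seed``."""

    out_dir: str
    generator: GeneratorConfig = dataclasses.field(
        default_factory=GeneratorConfig)
    region_dir: str | None = None     # load instead of simulate
    skip_simulate: bool = False
    make_plots: bool = False
    log_level: str = "INFO"
    domains: dict = dataclasses.field(
        default_factory=lambda: dict(DOMAIN_POLARITY))

    def __post_init__(self) -> None:
        goods = [d for d, p in self.domains.items() if p == "good"]
        bads = [d for d, p in self.domains.items() if p == "bad"]
        if len(goods) != 5 or len(bads) != 5:
            raise ConfigurationError(
                f"domain list must have exactly 5 goods and 5 bads, got "
                f"{len(goods)} goods / {len(bads)} bads")
        if set(self.domains) != set(DOMAIN_ORDER):
            raise ConfigurationError(
                "domain list must cover exactly the 10 documented domains")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML or JSON; keyword overrides win."""
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "generator" in raw and isinstance(raw["generator"], dict):
            raw["generator"] = GeneratorConfig(**raw["generator"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate/load -> access -> index -> summarise.

    Returns the manifest dict (also written to ``manifest.json``).  A stage
    failure halts the run, names the stage, and leaves a ``STALE`` marker
    flagging any partial outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "STALE"
    manifest: dict = {"seed": config.generator.seed,
                      "config": dataclasses.asdict(config),
                      "config_hash": config.config_hash(),
                      "stages": {}}
    stage = "simulate"
    try:
        stale.write_text("in progress: simulate\n")
        if config.skip_simulate or config.region_dir:
            src = config.region_dir or str(out / "region")
            region = read_region(src)
            logger.info("stage load: %d meshblocks from %s",
                        len(region.meshblocks), src)
        else:
            region = generate_region(config.generator)
            write_region(region, out / "region")
            logger.info("stage simulate: %d meshblocks",
                        len(region.meshblocks))
        manifest["stages"]["simulate"] = {"rows": len(region.meshblocks)}

        stage = "access"
        stale.write_text("in progress: access\n")
        table = build_access_table(region)
        write_access_table(table, out / "access.csv")
        n_fallback = int((table.provenance == "euclidean_fallback")
                         .to_numpy().sum())
        manifest["stages"]["access"] = {"rows": len(table.distances),
                                        "euclidean_fallback": n_fallback}
        logger.info("stage access: %d rows, %d fallback cells",
                    len(table.distances), n_fallback)

        stage = "index"
        stale.write_text("in progress: index\n")
        result = compute_hli(table)
        write_hli(result, out / "hli.csv")
        manifest["stages"]["index"] = {"rows": len(result.records)}
        logger.info("stage index: %d rows", len(result.records))

        stage = "summarise"
        stale.write_text("in progress: summarise\n")
        sdir = out / "summary"
        sdir.mkdir(exist_ok=True)
        mbf = region.meshblock_frame()
        grad = median_distance_by_deprivation(table, mbf)
        grad.medians.to_csv(sdir / "gradient_medians.csv",
                            index_label="group")
        grad.tests.to_csv(sdir / "gradient_tests.csv", index_label="domain")
        for grouping, name in (("none", "overall"),
                               ("dep_quintile", "by_quintile"),
                               ("urban_rural", "by_urban_rural")):
            shares = population_share_by_hli(result.records, mbf, grouping)
            shares.to_csv(sdir / f"shares_{name}.csv", index=False)
        rho = goods_bads_rank_correlation(result.composite, mbf,
                                          by="dep_quintile")
        rho.to_csv(sdir / "rank_correlation.csv", index_label="group")
        if config.make_plots:
            plot_share_bars(
                population_share_by_hli(result.records, mbf, "dep_quintile"),
                str(sdir / "shares_by_quintile.png"))
            plot_rank_scatter(result.composite, mbf,
                              str(sdir / "rank_scatter.png"))
        manifest["stages"]["summarise"] = {"rows": len(grad.medians)}
    except HLIError as exc:
        stale.write_text(f"failed at stage {stage}: {exc}\n")
        raise HLIError(f"stage {stage} failed: {exc}") from exc
    stale.unlink(missing_ok=True)
    _dump_json(manifest, out / "manifest.json")
    return manifest
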