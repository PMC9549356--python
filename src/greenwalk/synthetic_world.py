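"""Synthetic study area: terrain, land cover, buildings, and a street grid.

The generator produces a parameterized "grid city" whose layers have the
geometric and statistical structure the viewshed-based exposure computation
assumes: a coarse digital elevation model, a categorical land-cover raster
at 10 m resolution in which every cell carries exactly one class, building
footprints with a uniform height, and a rectangular street network.  All
layers share one planar coordinate frame in meters; no geographic CRS is
involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape


class ConfigError(ValueError):
    """Raised when a world configuration is internally inconsistent."""


# land-cover class codes (one integer per cell)
LANDCOVER_CLASSES = {
    "forest": 1,
    "low_vegetation": 2,
    "water": 3,
    "built_up": 4,
    "bare_soil": 5,
    "agriculture": 6,
}
GREEN_BLUE_CODES = frozenset({1, 2, 3})


@dataclass
class RasterGrid:
    """A regular raster in planar meters.

    ``values[0, :]`` is the northernmost row (ESRI ASCII grid convention);
    ``origin`` is the lower-left (xll, yll) corner of the grid extent.
    Values are located at cell centers for interpolation purposes.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 2-D array")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("all raster cells must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size,
                y0 + self.n_rows * self.cell_size)

    def xy_to_rc(self, x, y):
        """Fractional (row, col) cell-center coordinates of planar points."""
        x0, y0 = self.origin
        col = (np.asarray(x) - x0) / self.cell_size - 0.5
        ytop = y0 + self.n_rows * self.cell_size
        row = (ytop - np.asarray(y)) / self.cell_size - 0.5
        return row, col

    def cell_index(self, x, y):
        """Integer (row, col) of the cell containing each point."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        ytop = y0 + self.n_rows * self.cell_size
        row = np.floor((ytop - np.asarray(y)) / self.cell_size).astype(int)
        return (np.clip(row, 0, self.n_rows - 1),
                np.clip(col, 0, self.n_cols - 1))

    def cell_center(self, row, col):
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        ytop = y0 + self.n_rows * self.cell_size
        y = ytop - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def sample_bilinear(self, x, y):
        """Bilinear interpolation of cell-center values; edges are clamped."""
        row, col = self.xy_to_rc(x, y)
        return ndimage.map_coordinates(
            self.values.astype(float), [np.atleast_1d(row), np.atleast_1d(col)],
            order=1, mode="nearest",
        ).reshape(np.shape(x))


@dataclass
class LandCoverRaster:
    """Integer-coded land cover; every cell belongs to exactly one class."""

    grid: RasterGrid
    classes: dict[str, int] = field(default_factory=lambda: dict(LANDCOVER_CLASSES))

    def __post_init__(self) -> None:
        codes = set(self.classes.values())
        present = set(np.unique(self.grid.values).tolist())
        if not present <= codes:
            raise ValueError(f"unknown land-cover codes: {present - codes}")

    def class_fractions(self) -> dict[str, float]:
        n = self.grid.values.size
        counts = {name: int(np.sum(self.grid.values == code))
                  for name, code in self.classes.items()}
        return {name: c / n for name, c in counts.items()}

    def class_areas(self) -> dict[str, float]:
        """Per-class area in m2; the values partition the raster extent."""
        a = self.grid.cell_size ** 2
        return {name: float(np.sum(self.grid.values == code)) * a
                for name, code in self.classes.items()}

    def green_blue_fraction(self) -> float:
        mask = np.isin(self.grid.values, list(GREEN_BLUE_CODES))
        return float(mask.mean())


@dataclass
class BuildingSet:
    footprints: list[Polygon]
    uniform_height: float = 8.0

    def __post_init__(self) -> None:
        if self.uniform_height <= 0:
            raise ValueError("building height must be > 0")
        for p in self.footprints:
            if (not p.is_valid) or p.is_empty or p.area <= 0:
                raise ValueError("building footprints must be simple, "
                                 "non-degenerate polygons")


@dataclass
class StreetNetwork:
    """Planar street graph: node coordinates and node-index edge pairs."""

    nodes: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(self.nodes) < 2:
            raise ValueError("street network needs at least 2 nodes")

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) coordinate arrays of all edge segments."""
        return self.nodes[self.edges[:, 0]], self.nodes[self.edges[:, 1]]

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for i, j in self.edges:
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
        return adj


@dataclass
class World:
    boundary: tuple[float, float, float, float]
    dem: RasterGrid
    landcover: LandCoverRaster
    buildings: BuildingSet
    streets: StreetNetwork

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.boundary
        nx, ny = self.streets.nodes[:, 0], self.streets.nodes[:, 1]
        if (nx.min() < x0 - 1e-9 or nx.max() > x1 + 1e-9
                or ny.min() < y0 - 1e-9 or ny.max() > y1 + 1e-9):
            raise ValueError("street nodes must lie inside the boundary")


@dataclass
class WorldConfig:
    """Parameters of the synthetic study area.

    ``class_mix`` gives target land-cover proportions; realized cell shares
    land within ±2 percentage points of the targets (assignment is by
    quantiles of a smoothed random field, so patches are contiguous).  The
    default green+blue mix is 34%, the building height 8 m, and the terrain
    a smooth low-relief surface (≤ 10 m over the extent) — each an explicit
    assumption, configurable for sensitivity analyses.
    """

    width: float = 1000.0
    height: float = 1000.0
    street_spacing: float = 100.0
    landcover_cell: float = 10.0
    dem_cell: float = 25.0
    dem_relief: float = 10.0
    dem_base: float = 300.0
    building_height: float = 8.0
    building_density: float = 0.5
    building_size: float = 6.0
    patch_scale_cells: float = 5.0
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "forest": 0.20,
        "low_vegetation": 0.135,
        "water": 0.005,
        "built_up": 0.40,
        "bare_soil": 0.06,
        "agriculture": 0.20,
    })


# quantile order along the smoothed field: water sits inside forest,
# built-up at the opposite end so green forms contiguous patches
_CLASS_ORDER = ["water", "forest", "low_vegetation",
                "agriculture", "bare_soil", "built_up"]


def generate_world(config: WorldConfig, seed: int) -> World:
    """Generate a reproducible synthetic study area.

    Pure function of ``(config, seed)``: the same pair yields byte-identical
    layers.  Land-cover class proportions are realized within ±2 percentage
    points of the configured mix, and no building footprint overlaps a
    street node.
    """
    rng = np.random.default_rng(seed)
    x0 = y0 = 0.0
    x1, y1 = float(config.width), float(config.height)
    nc = int(round(config.width / config.landcover_cell))
    nr = int(round(config.height / config.landcover_cell))
    if nr * nc < 4:
        raise ConfigError("boundary must cover at least 4 land-cover cells")
    mix = dict(config.class_mix)
    total = sum(mix.get(k, 0.0) for k in _CLASS_ORDER)
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ConfigError(f"class_mix must sum to 1, got {total}")

    # --- land cover: quantile-sliced smooth field ---
    fld = ndimage.gaussian_filter(rng.standard_normal((nr, nc)),
                                  config.patch_scale_cells)
    order = np.argsort(fld.ravel(), kind="stable")
    codes = np.empty(nr * nc, dtype=np.int16)
    start = 0
    counts = _apportion(nr * nc, [mix.get(k, 0.0) for k in _CLASS_ORDER])
    for name, cnt in zip(_CLASS_ORDER, counts):
        codes[order[start:start + cnt]] = LANDCOVER_CLASSES[name]
        start += cnt
    landcover = LandCoverRaster(
        RasterGrid((x0, y0), config.landcover_cell, codes.reshape(nr, nc)))

    # --- terrain: smooth low-relief noise ---
    dnc = max(2, int(round(config.width / config.dem_cell)))
    dnr = max(2, int(round(config.height / config.dem_cell)))
    z = ndimage.gaussian_filter(rng.standard_normal((dnr, dnc)), 3.0)
    zmin, zmax = z.min(), z.max()
    if zmax > zmin:
        z = (z - zmin) / (zmax - zmin) * config.dem_relief
    dem = RasterGrid((x0, y0), config.dem_cell, z + config.dem_base)

    # --- street grid ---
    xs = np.arange(x0, x1 + 1e-9, config.street_spacing)
    ys = np.arange(y0, y1 + 1e-9, config.street_spacing)
    nodes = np.array([(x, y) for y in ys for x in xs])
    idx = lambda i, j: i * len(xs) + j  # noqa: E731
    edges = []
    for i in range(len(ys)):
        for j in range(len(xs)):
            if j + 1 < len(xs):
                edges.append((idx(i, j), idx(i, j + 1)))
            if i + 1 < len(ys):
                edges.append((idx(i, j), idx(i + 1, j)))
    streets = StreetNetwork(nodes, np.array(edges))

    # --- buildings inside built-up cells, clear of street nodes ---
    footprints = []
    half = config.building_size / 2.0
    built_rows, built_cols = np.where(
        landcover.grid.values == LANDCOVER_CLASSES["built_up"])
    place = rng.random(built_rows.size) < config.building_density
    jitter = rng.uniform(-0.15, 0.15, (built_rows.size, 2)) * config.landcover_cell
    for k in np.flatnonzero(place):
        cx, cy = landcover.grid.cell_center(built_rows[k], built_cols[k])
        cx, cy = cx + jitter[k, 0], cy + jitter[k, 1]
        _, d = nearest_street_point_coords(nodes, np.array(edges), (cx, cy))
        if d <= half * 1.5:  # keep streets clear
            continue
        footprints.append(Polygon([
            (cx - half, cy - half), (cx + half, cy - half),
            (cx + half, cy + half), (cx - half, cy + half)]))
    buildings = BuildingSet(footprints, config.building_height)

    return World((x0, y0, x1, y1), dem, landcover, buildings, streets)


def _apportion(n: int, shares: list[float]) -> list[int]:
    """Integer cell counts with largest-remainder rounding (sums to n)."""
    raw = [s * n for s in shares]
    base = [int(math.floor(r)) for r in raw]
    rem = n - sum(base)
    frac_order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i],
                        reverse=True)
    for i in frac_order[:rem]:
        base[i] += 1
    return base


def nearest_street_point(streets: StreetNetwork,
                         p: tuple[float, float]) -> tuple[tuple[float, float], float]:
    """Closest point on any street edge segment and its Euclidean distance.

    The projection considers segment interiors, not only nodes; exact
    distance ties are broken in favour of the lowest edge index.
    """
    if streets is None or len(streets.edges) == 0:
        raise ValueError("street network is empty")
    return nearest_street_point_coords(streets.nodes, streets.edges, p)


def nearest_street_point_coords(nodes: np.ndarray, edges: np.ndarray,
                                p) -> tuple[tuple[float, float], float]:
    a, b = nodes[edges[:, 0]], nodes[edges[:, 1]]
    p = np.asarray(p, dtype=float)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("j,ij->i", p, ab) - np.einsum("ij,ij->i", a, ab), 0,
                denom) / denom
    q = a + t[:, None] * ab
    d = np.hypot(q[:, 0] - p[0], q[:, 1] - p[1])
    k = int(np.argmin(d))  # argmin returns the first (lowest-index) minimum
    return (float(q[k, 0]), float(q[k, 1])), float(d[k])


# ---------------------------------------------------------------------------
# plain-text IO: ESRI ASCII grids and GeoJSON
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    x0, y0 = grid.origin
    header = (f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
              f"xllcorner {x0}\nyllcorner {y0}\n"
              f"cellsize {grid.cell_size}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    return RasterGrid((meta["xllcorner"], meta["yllcorner"]),
                      meta["cellsize"], np.atleast_2d(values))


def buildings_to_geojson(buildings: BuildingSet) -> dict:
    feats = [{"type": "Feature",
              "properties": {"height": buildings.uniform_height},
              "geometry": mapping(p)} for p in buildings.footprints]
    return {"type": "FeatureCollection", "features": feats}


def buildings_from_geojson(doc: dict) -> BuildingSet:
    feats = doc.get("features", [])
    height = feats[0]["properties"]["height"] if feats else 8.0
    return BuildingSet([shape(f["geometry"]) for f in feats], height)


def streets_to_geojson(streets: StreetNetwork) -> dict:
    a, b = streets.segments
    feats = [{"type": "Feature", "properties": {"edge": int(k)},
              "geometry": {"type": "LineString",
                           "coordinates": [list(a[k]), list(b[k])]}}
             for k in range(len(streets.edges))]
    return {"type": "FeatureCollection", "features": feats}


def streets_from_geojson(doc: dict) -> StreetNetwork:
    nodes: list[tuple[float, float]] = []
    index: dict[tuple[float, float], int] = {}
    edges = []
    for f in doc["features"]:
        (xa, ya), (xb, yb) = f["geometry"]["coordinates"]
        ids = []
        for pt in ((xa, ya), (xb, yb)):
            key = (round(pt[0], 6), round(pt[1], 6))
            if key not in index:
                index[key] = len(nodes)
                nodes.append(pt)
            ids.append(index[key])
        edges.append(tuple(ids))
    return StreetNetwork(np.array(nodes), np.array(edges))


def write_world(world: World, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(world.dem, out / "dem.asc")
    write_ascii_grid(world.landcover.grid, out / "landcover.asc")
    (out / "buildings.geojson").write_text(
        json.dumps(buildings_to_geojson(world.buildings)))
    (out / "streets.geojson").write_text(
        json.dumps(streets_to_geojson(world.streets)))
    (out / "world.json").write_text(json.dumps({
        "boundary": list(world.boundary),
        "classes": world.landcover.classes,
    }))


def read_world(in_dir: str | Path) -> World:
    d = Path(in_dir)
    meta = json.loads((d / "world.json").read_text())
    dem = read_ascii_grid(d / "dem.asc")
    lc_grid = read_ascii_grid(d / "landcover.asc")
    lc_grid.values = lc_grid.values.astype(np.int16)
    return World(
        tuple(meta["boundary"]), dem,
        LandCoverRaster(lc_grid, {k: int(v) for k, v in meta["classes"].items()}),
        buildings_from_geojson(json.loads((d / "buildings.geojson").read_text())),
        streets_from_geojson(json.loads((d / "streets.geojson").read_text())),
    )
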