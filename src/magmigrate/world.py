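"""World geography: habitat rasters, coastlines, natal and goal regions.

The simulation world is a 1-degree-by-1-degree cell-registered raster
(EPSG:4326-style geographic grid) carrying a land mask, vegetation
fraction, low-vegetation fraction, barren fraction and an NDVI proxy; a
~20-km-spaced coastal point set on the land/sea boundary; and lat/lon boxes
for the natal (breeding) and goal (wintering) regions. Worlds are either
generated synthetically from a box-based spec (standing in for real
land-cover data) or round-tripped through ESRI ASCII grid text rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .geodesy import EARTH_RADIUS_KM

__all__ = [
    "Box",
    "LandBlock",
    "SyntheticWorldSpec",
    "World",
    "make_synthetic_world",
    "sample_natal_locations",
    "is_barren",
    "detection_probability",
    "nearest_viewable_coast",
    "write_ascii_grid",
    "read_ascii_grid",
]

KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0  # ~111.195 km per degree of arc
MAX_DETECTION_KM = 300.0
COAST_SPACING_KM = 20.0


@dataclass(frozen=True)
class Box:
    """A lat/lon rectangle (degrees); bounds inclusive of min, exclusive of max."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError(f"degenerate box: {self}")

    def contains(self, lat, lon):
        lat = np.asarray(lat)
        lon = np.asarray(lon)
        return (
            (lat >= self.lat_min) & (lat < self.lat_max)
            & (lon >= self.lon_min) & (lon < self.lon_max)
        )

    def overlaps(self, other: "Box") -> bool:
        return not (
            self.lat_max <= other.lat_min or other.lat_max <= self.lat_min
            or self.lon_max <= other.lon_min or other.lon_max <= self.lon_min
        )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.lat_min + self.lat_max), 0.5 * (self.lon_min + self.lon_max))


@dataclass(frozen=True)
class LandBlock:
    """A rectangular landmass with mean habitat properties."""

    box: Box
    vegetation: float = 0.5     # mean vegetated fraction per cell
    low_vegetation: float = 0.3  # mean low (open) vegetation fraction
    barren: float = 0.05        # mean barren fraction
    ndvi: float = 0.5           # NDVI proxy (scalar per cell)
    name: str = "land"


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Recipe for a fully synthetic world raster.

    ``barren_patch_fraction`` of land cells are turned into barren desert
    (zero vegetation and NDVI), emulating patchy unsuitable habitat.
    ``habitat_noise`` jitters per-cell habitat fractions around the block
    means so natal-cell qualification is non-trivial.
    """

    domain: Box
    land_blocks: tuple
    natal_region: Box
    goal_region: Box
    cell_deg: float = 1.0
    barren_patch_fraction: float = 0.02
    habitat_noise: float = 0.1
    name: str = "synthetic"

    def __post_init__(self):
        if self.natal_region.overlaps(self.goal_region):
            raise ValueError("natal and goal regions must not overlap")
        if not self.land_blocks:
            raise ValueError("at least one land block required")
        blocks = tuple(self.land_blocks)
        if not any(b.box.overlaps(self.natal_region) for b in blocks):
            raise ValueError("no land block intersects the natal region")
        if not any(b.box.overlaps(self.goal_region) for b in blocks):
            raise ValueError("no land block intersects the goal region")
        object.__setattr__(self, "land_blocks", blocks)


class World:
    """Gridded world with land/habitat layers, coastal points and regions."""

    def __init__(self, lat0, lon0, cell_deg, land, vegetation, low_vegetation,
                 barren, ndvi, natal_region: Box, goal_region: Box, name="world"):
        self.lat0 = float(lat0)     # south edge of the grid
        self.lon0 = float(lon0)     # west edge of the grid
        self.cell_deg = float(cell_deg)
        self.land = np.asarray(land, dtype=bool)
        self.vegetation = np.asarray(vegetation, dtype=float)
        self.low_vegetation = np.asarray(low_vegetation, dtype=float)
        self.barren = np.asarray(barren, dtype=float)
        self.ndvi = np.asarray(ndvi, dtype=float)
        self.natal_region = natal_region
        self.goal_region = goal_region
        self.name = name
        self.nlat, self.nlon = self.land.shape
        self.coast_lat, self.coast_lon = self._build_coastal_points()
        self._coast_tree = cKDTree(_unit_vectors(self.coast_lat, self.coast_lon))

    # -- grid lookups -------------------------------------------------------

    def cell_index(self, lat, lon):
        """Row/col indices; -1 where outside the raster domain."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat0) / self.cell_deg).astype(int)
        j = np.floor((lon - self.lon0) / self.cell_deg).astype(int)
        bad = (i < 0) | (i >= self.nlat) | (j < 0) | (j >= self.nlon)
        return np.where(bad, -1, i), np.where(bad, -1, j)

    def is_land(self, lat, lon):
        """True over land cells; positions outside the domain count as sea."""
        i, j = self.cell_index(lat, lon)
        ok = (i >= 0) & (j >= 0)
        out = np.zeros(np.shape(ok), dtype=bool)
        out[ok] = self.land[i[ok], j[ok]]
        if out.shape == ():
            return bool(out)
        return out

    def barren_at(self, lat, lon):
        """Vectorized barren flag (no refuelling); sea positions are False."""
        i, j = self.cell_index(lat, lon)
        ok = (i >= 0) & (j >= 0)
        out = np.zeros(np.shape(ok), dtype=bool)
        iv, jv = i[ok], j[ok]
        out[ok] = self.land[iv, jv] & (
            (self.vegetation[iv, jv] <= 0.0) | (self.ndvi[iv, jv] <= 0.0)
        )
        if out.shape == ():
            return bool(out)
        return out

    # -- coastline ----------------------------------------------------------

    def _build_coastal_points(self):
        """Points every ~20 km along land/sea cell boundaries."""
        lats, lons = [], []
        land = self.land
        padded = np.zeros((self.nlat + 2, self.nlon + 2), dtype=bool)
        padded[1:-1, 1:-1] = land
        sea_n = ~padded[2:, 1:-1]
        sea_s = ~padded[:-2, 1:-1]
        sea_e = ~padded[1:-1, 2:]
        sea_w = ~padded[1:-1, :-2]
        cd = self.cell_deg
        for i, j in zip(*np.nonzero(land)):
            south = self.lat0 + i * cd
            west = self.lon0 + j * cd
            north, east = south + cd, west + cd
            if sea_n[i, j]:  # northern edge, runs along a parallel
                self._edge_points(lats, lons, north, west, north, east, along_lat=True)
            if sea_s[i, j]:
                self._edge_points(lats, lons, south, west, south, east, along_lat=True)
            if sea_e[i, j]:
                self._edge_points(lats, lons, south, east, north, east, along_lat=False)
            if sea_w[i, j]:
                self._edge_points(lats, lons, south, west, north, west, along_lat=False)
        if not lats:
            raise ValueError("world has no coastline (all land or all sea)")
        return np.asarray(lats), np.asarray(lons)

    def _edge_points(self, lats, lons, lat_a, lon_a, lat_b, lon_b, along_lat):
        if along_lat:
            length = abs(lon_b - lon_a) * KM_PER_DEG * math.cos(math.radians(lat_a))
        else:
            length = abs(lat_b - lat_a) * KM_PER_DEG
        npts = max(1, int(round(length / COAST_SPACING_KM)))
        f = (np.arange(npts) + 0.5) / npts
        lats.extend(lat_a + f * (lat_b - lat_a))
        lons.extend(lon_a + f * (lon_b - lon_a))

    def nearest_coast(self, lat, lon):
        """(distance_km, coastal index) of the nearest coastal point(s)."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        chord, idx = self._coast_tree.query(_unit_vectors(lat, lon))
        dist = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
        return dist, idx

    @property
    def cell_coast_distance_km(self) -> np.ndarray:
        """Distance from each cell centre to the nearest coastal point (cached)."""
        if getattr(self, "_cell_coast_dist", None) is None:
            glat, glon = self.cell_centers()
            d, _ = self.nearest_coast(glat.ravel(), glon.ravel())
            self._cell_coast_dist = d.reshape(self.nlat, self.nlon)
        return self._cell_coast_dist

    def coast_distance_approx(self, lat, lon) -> np.ndarray:
        """Cell-resolution distance to coast; +inf outside the raster domain."""
        i, j = self.cell_index(lat, lon)
        ok = (i >= 0) & (j >= 0)
        out = np.full(np.shape(ok), np.inf)
        grid = self.cell_coast_distance_km
        out[ok] = grid[i[ok], j[ok]]
        return out

    # -- regions ------------------------------------------------------------

    def natal_qualifying_mask(self):
        """Land cells inside the natal region suitable as breeding habitat.

        The rule: at least 10% low (open) vegetation and under 15% barren
        habitat within the 1-degree cell.
        """
        cd = self.cell_deg
        clat = self.lat0 + (np.arange(self.nlat) + 0.5) * cd
        clon = self.lon0 + (np.arange(self.nlon) + 0.5) * cd
        glat, glon = np.meshgrid(clat, clon, indexing="ij")
        in_region = self.natal_region.contains(glat, glon)
        return in_region & self.land & (self.low_vegetation >= 0.10) & (self.barren < 0.15)

    def cell_centers(self):
        cd = self.cell_deg
        clat = self.lat0 + (np.arange(self.nlat) + 0.5) * cd
        clon = self.lon0 + (np.arange(self.nlon) + 0.5) * cd
        return np.meshgrid(clat, clon, indexing="ij")

    # -- persistence --------------------------------------------------------

    _LAYERS = ("land", "vegetation", "low_vegetation", "barren", "ndvi")

    def save(self, directory):
        """Export as a directory of ESRI ASCII grids plus a YAML header."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for layer in self._LAYERS:
            write_ascii_grid(directory / f"{layer}.asc", getattr(self, layer).astype(float),
                             self.lat0, self.lon0, self.cell_deg)
        meta = {
            "format_version": 1,
            "name": self.name,
            "natal_region": _box_to_list(self.natal_region),
            "goal_region": _box_to_list(self.goal_region),
        }
        (directory / "world.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "World":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "world.yaml").read_text())
        layers = {}
        geo = None
        for layer in cls._LAYERS:
            arr, lat0, lon0, cell = read_ascii_grid(directory / f"{layer}.asc")
            layers[layer] = arr
            geo = (lat0, lon0, cell)
        layers["land"] = layers["land"] > 0.5
        return cls(
            *geo,
            land=layers["land"], vegetation=layers["vegetation"],
            low_vegetation=layers["low_vegetation"], barren=layers["barren"],
            ndvi=layers["ndvi"],
            natal_region=Box(*meta["natal_region"]),
            goal_region=Box(*meta["goal_region"]),
            name=meta.get("name", "world"),
        )


def _unit_vectors(lat, lon):
    la = np.deg2rad(np.asarray(lat, dtype=float))
    lo = np.deg2rad(np.asarray(lon, dtype=float))
    return np.column_stack((np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)))


def _box_to_list(box: Box):
    return [box.lat_min, box.lat_max, box.lon_min, box.lon_max]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def detection_probability(distance_km):
    """Probability of spotting land at a given distance: max(0, 1 - d/300).

    Certain on the coast, 50% at 150 km, impossible at and beyond 300 km.
    """
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    p = np.maximum(0.0, 1.0 - d / MAX_DETECTION_KM)
    if p.shape == ():
        return float(p)
    return p


def nearest_viewable_coast(world: World, track_points, rng):
    """First coastal point detected from a sequence of over-flight positions.

    ``track_points`` are (lat, lon) pairs, ordered along the flight (the
    dawn rule samples the last three deciles plus the endpoint). Each point
    gets an independent Bernoulli detection trial with probability
    ``detection_probability`` of its distance to the nearest coastal point;
    the first success returns that coastal point's (lat, lon), else None.
    """
    pts = np.atleast_2d(np.asarray(track_points, dtype=float))
    dist, idx = world.nearest_coast(pts[:, 0], pts[:, 1])
    for k in range(len(pts)):
        p = detection_probability(dist[k])
        if p > 0.0 and rng.random() < p:
            return float(world.coast_lat[idx[k]]), float(world.coast_lon[idx[k]])
    return None


def is_barren(world: World, location) -> bool:
    """True when the cell at ``location`` offers no refuelling habitat.

    Barren means zero vegetated fraction or non-positive NDVI proxy within
    the 1-degree cell. Raises for ocean locations.
    """
    lat, lon = location
    if not world.is_land(lat, lon):
        raise ValueError(f"location {location} is not on land")
    return bool(world.barren_at(lat, lon))


def sample_natal_locations(world: World, n: int, rng):
    """Fixed natal point locations: uniform over qualifying natal-region cells.

    Cells are weighted by their true (cos-latitude) area; points fall
    uniformly within their cell. Returns (lat, lon) arrays of length n.
    The same locations are reused for every simulated year.
    """
    mask = world.natal_qualifying_mask()
    ii, jj = np.nonzero(mask)
    if len(ii) == 0:
        raise ValueError("no qualifying natal cells in the natal region")
    cd = world.cell_deg
    cell_lat = world.lat0 + (ii + 0.5) * cd
    weights = np.cos(np.deg2rad(cell_lat))
    weights = weights / weights.sum()
    pick = rng.choice(len(ii), size=n, p=weights)
    lat = world.lat0 + (ii[pick] + rng.uniform(0.0, 1.0, n)) * cd
    lon = world.lon0 + (jj[pick] + rng.uniform(0.0, 1.0, n)) * cd
    return lat, lon


def make_synthetic_world(spec: SyntheticWorldSpec, rng) -> World:
    """Rasterize a synthetic world spec (deterministic for a fixed seed)."""
    dom = spec.domain
    cd = spec.cell_deg
    nlat = int(round((dom.lat_max - dom.lat_min) / cd))
    nlon = int(round((dom.lon_max - dom.lon_min) / cd))
    land = np.zeros((nlat, nlon), dtype=bool)
    veg = np.zeros((nlat, nlon))
    low = np.zeros((nlat, nlon))
    barren = np.zeros((nlat, nlon))
    ndvi = np.zeros((nlat, nlon))
    clat = dom.lat_min + (np.arange(nlat) + 0.5) * cd
    clon = dom.lon_min + (np.arange(nlon) + 0.5) * cd
    glat, glon = np.meshgrid(clat, clon, indexing="ij")
    for block in spec.land_blocks:
        sel = block.box.contains(glat, glon)
        land |= sel
        noise = spec.habitat_noise
        veg[sel] = np.clip(block.vegetation + noise * rng.standard_normal(sel.sum()), 0.01, 1.0)
        low[sel] = np.clip(block.low_vegetation + noise * rng.standard_normal(sel.sum()), 0.0, 1.0)
        barren[sel] = np.clip(block.barren + 0.5 * noise * rng.standard_normal(sel.sum()), 0.0, 1.0)
        ndvi[sel] = np.clip(block.ndvi + noise * rng.standard_normal(sel.sum()), 0.01, 1.0)
    if spec.barren_patch_fraction > 0.0:
        patches = land & (rng.random((nlat, nlon)) < spec.barren_patch_fraction)
        veg[patches] = 0.0
        ndvi[patches] = 0.0
        barren[patches] = 1.0
        low[patches] = 0.0
    return World(dom.lat_min, dom.lon_min, cd, land, veg, low, barren, ndvi,
                 natal_region=spec.natal_region, goal_region=spec.goal_region,
                 name=spec.name)


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO (text raster format; cell-registered geographic grid)
# ---------------------------------------------------------------------------


def write_ascii_grid(path, array, lat0, lon0, cell_deg, nodata=-9999.0):
    """Write an ESRI ASCII grid; row 1 of the file is the northernmost row."""
    arr = np.asarray(array, dtype=float)
    nlat, nlon = arr.shape
    lines = [
        f"ncols {nlon}",
        f"nrows {nlat}",
        f"xllcorner {lon0}",
        f"yllcorner {lat0}",
        f"cellsize {cell_deg}",
        f"NODATA_value {nodata}",
    ]
    for row in arr[::-1]:
        lines.append(" ".join(format(v, ".10g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array, lat0, lon0, cell_deg)."""
    text = Path(path).read_text().split("\n")
    header = {}
    i = 0
    while i < len(text):
        tokens = text[i].split()
        if len(tokens) == 2 and tokens[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[tokens[0].lower()] = float(tokens[1])
            i += 1
        else:
            break
    rows = []
    for line in text[i:]:
        if line.strip():
            rows.append([float(tok) for tok in line.split()])
    arr = np.asarray(rows)[::-1]
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    return arr, header["yllcorner"], header["xllcorner"], header["cellsize"]
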